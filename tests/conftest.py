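import numpy as np
import pandas as pd
import pytest

from cdk9sig import diffexpr, preprocess, synthetic


@pytest.fixture(scope="session")
def treatment_sim():
    """Small treated/untreated experiment with known truth."""
    cfg = synthetic.TreatmentSimConfig(seed=42, n_genes=400, samples_per_arm=3)
    return synthetic.simulate_treatment_experiment(cfg)


@pytest.fixture(scope="session")
def treatment_norm(treatment_sim):
    cm, design, truth = treatment_sim
    filt = preprocess.filter_low_expression(cm)
    sf = preprocess.control_size_factors(filt)
    return preprocess.normalize_counts(filt, sf), design, truth


@pytest.fixture(scope="session")
def treatment_de(treatment_norm):
    """DE results for the standard contrasts of the small experiment."""
    nm, design, truth = treatment_norm
    out = {}
    for key, a, b in [
        ("treatment_ps", "untreated-PS", "NVP2-PS"),
        ("treatment_rs", "untreated-RS", "NVP2-RS"),
        ("activation_rs", "unstimulated", "untreated-RS"),
    ]:
        disp = diffexpr.estimate_dispersions(nm, design, a, b)
        out[key] = diffexpr.nb_wald_test(nm, design, disp, a, b)
    return out


@pytest.fixture(scope="session")
def cohort_sim():
    cfg = synthetic.CohortSimConfig(
        seed=7, n_genes=3000,
        n_per_group={"HC": 8, "responder": 12, "non-responder": 12},
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def chip_sim():
    cfg = synthetic.ChipSimConfig(seed=3, n_genes=400)
    return synthetic.simulate_chip(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_de_frame(log2fc, wald_p=None, fdr=None, genes=None):
    """Convenience DE-shaped frame for table-level operations."""
    log2fc = np.asarray(log2fc, dtype=float)
    n = len(log2fc)
    if genes is None:
        genes = [f"g{i:04d}" for i in range(n)]
    wald_p = np.full(n, 0.5) if wald_p is None else np.asarray(wald_p, dtype=float)
    fdr = wald_p if fdr is None else np.asarray(fdr, dtype=float)
    return pd.DataFrame(
        {
            "base_mean": np.full(n, 100.0),
            "log2fc": log2fc,
            "se": np.full(n, 0.1),
            "wald_p": wald_p,
            "fdr": fdr,
            "dispersion": np.full(n, 0.05),
        },
        index=pd.Index(genes, name="gene"),
    )
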