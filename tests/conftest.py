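import pandas as pd
import pytest

from sahelcc.calibrate import paper_default
from sahelcc.pipeline import run_pipeline


def _load(out_dir, names):
    return {n: pd.read_csv(f"{out_dir}/{n}.csv") for n in names}


ARTIFACTS = ("cells", "balance", "regional_sd", "decadal_summary", "trends", "demand", "supply", "seasons")


@pytest.fixture(scope="session")
def reference_run_noise_free(tmp_path_factory):
    """Calibrated reference scenario, 500 cells x 1981-2020, all noise off."""
    out = tmp_path_factory.mktemp("ref_nf")
    cfg = paper_default(seed=1202, noise=False, out_dir=str(out))
    cfg.write_breakdown = False
    run_pipeline(cfg)
    return _load(out, ARTIFACTS)


@pytest.fixture(scope="session")
def reference_run_noisy(tmp_path_factory):
    """Same scenario with lognormal precipitation noise (sigma 0.15) on."""
    out = tmp_path_factory.mktemp("ref_noisy")
    cfg = paper_default(seed=1202, noise=True, out_dir=str(out))
    cfg.write_breakdown = False
    run_pipeline(cfg)
    return _load(out, ARTIFACTS)
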