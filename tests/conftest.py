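"""Shared fixtures: phantoms, cohorts, and pipeline runs reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from atflseg.imgio import ROISpec, crop_roi
from atflseg.phantom import DEFAULT_ROI, PhantomSpec, make_cohort
from atflseg.pipeline import PipelineConfig, run_pipeline


def disk_image(n: int = 64, radius: float = 20.0, inside: int = 200, outside: int = 50):
    """Noise-free disk phantom with known truth (used by level-set tests)."""
    rr, cc = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2
    truth = (rr - c) ** 2 + (cc - c) ** 2 <= radius**2
    return np.where(truth, inside, outside).astype(np.uint8), truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160202)


@pytest.fixture(scope="session")
def clinical_cohort():
    """Speckled cohort matching the clinical group split (12/8/5)."""
    return make_cohort({"normal": 12, "tear": 8, "thickened": 5}, seed=11)


@pytest.fixture(scope="session")
def default_roi():
    return ROISpec(*DEFAULT_ROI)


@pytest.fixture(scope="session")
def cohort_runs(clinical_cohort, default_roi):
    """Default-config pipeline results over the whole cohort (the expensive
    shared computation behind the end-to-end properties)."""
    cfg = PipelineConfig(roi=default_roi, seed=5)
    runs = []
    for img, truth, group in clinical_cohort:
        tsub = crop_roi(truth.astype(np.uint8), default_roi).astype(bool)
        res = run_pipeline(img, cfg, truth=tsub)
        runs.append((res, tsub, group))
    return runs


@pytest.fixture(scope="session")
def cohort_runs_long(clinical_cohort, default_roi):
    """Same cohort at a doubled Chan-Vese iteration cap (1600)."""
    from dataclasses import replace

    cfg = PipelineConfig(roi=default_roi, seed=5)
    cfg = replace(cfg, cv=replace(cfg.cv, max_iterations=1600))
    return [run_pipeline(img, cfg) for img, _, _ in clinical_cohort]


@pytest.fixture()
def clean_spec():
    """Noise-free, drift-free, blur-free phantom spec (the analytic limit)."""
    return PhantomSpec(speckle_looks=None, blur_sigma=0.0, contrast_drift=0.0)
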