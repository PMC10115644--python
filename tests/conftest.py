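"""Shared fixtures: a midsize synthetic study generated once per session.

The ``study`` fixture carries a 400-participant cohort with fitted
metabolomics/proteomics ensembles and hold-out predictions, so that the
health-classification, microbiome and network tests can interrogate one
consistent dataset instead of refitting per test.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from omicsbmi import health_classes as hc
from omicsbmi import inferred_bmi as ib
from omicsbmi.preprocess import zscore
from omicsbmi import synthetic_cohort as sc


@pytest.fixture(scope="session")
def study_config() -> sc.GeneratorConfig:
    return sc.GeneratorConfig(n_participants=400, seed=11)


@pytest.fixture(scope="session")
def study(study_config):
    omics, meta, truth = sc.generate_baseline_cohort(study_config)
    plan = ib.make_split_plan(meta, k=10, seed=11)
    prepared, stats, ensembles, predictions = {}, {}, {}, {}
    for cat in ("metabolomics", "proteomics", "chemistries"):
        z, st = zscore(omics[cat].values)
        prepared[cat] = z
        stats[cat] = st
    for cat in ("metabolomics", "proteomics"):
        ens, pred = ib.fit_cv_lasso_ensemble(
            prepared[cat], meta["bmi"], plan, category=cat,
            standardization=stats[cat])
        ensembles[cat] = ens
        predictions[cat] = pred
    measured_class = hc.who_bmi_class(meta["bmi"])
    mets = hc.mets_risk_table(meta)
    return SimpleNamespace(
        config=study_config, omics=omics, meta=meta, truth=truth, plan=plan,
        prepared=prepared, stats=stats, ensembles=ensembles,
        predictions=predictions, measured_class=measured_class, mets=mets)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
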