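"""Shared fixtures: phantoms and cohorts generated once per session.

All inputs are produced programmatically by the synthetic-data module;
nothing is read from disk. Expensive end-to-end artefacts (the default
phantom, the grading cohort, the matching pairs, the longitudinal
series) are session-scoped so unit and acceptance tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from replicamap.grading import build_cohort, make_splits
from replicamap.longitudinal import build_series, tumour_abundance
from replicamap.matching import mean_tissue_spectrum
from replicamap.pipeline import standard_preprocess
from replicamap.preprocess import BinAxis
from replicamap.simulate import (
    CohortSpec,
    LongitudinalSpec,
    PhantomSpec,
    generate_cohort,
    generate_longitudinal,
    generate_section,
    truth_region_labels,
)

ANALYSIS_AXIS = BinAxis(600.0, 900.0, 0.5)


def nearest_feature(axis_mz: np.ndarray, mz: float) -> float:
    """Feature value on an axis closest to a requested m/z."""
    return float(axis_mz[int(np.argmin(np.abs(axis_mz - mz)))])


@pytest.fixture(scope="session")
def axis05() -> BinAxis:
    return ANALYSIS_AXIS


@pytest.fixture(scope="session")
def phantom():
    """Default three-region 64×64 phantom plus its preprocessed artefacts."""
    spec = PhantomSpec(seed=5)
    dataset, truth = generate_section(spec)
    result = standard_preprocess(dataset, axis=ANALYSIS_AXIS)
    return {"spec": spec, "dataset": dataset, "truth": truth, "result": result}


@pytest.fixture(scope="session")
def grading_cohort():
    """23-patient strong-effect cohort, preprocessed, with splits."""
    spec = CohortSpec(seed=1)
    sections, replicas, metadata = generate_cohort(spec)
    sec_items, rep_items = [], []
    for (sds, _), (rds, _) in zip(sections, replicas):
        sres = standard_preprocess(sds, axis=ANALYSIS_AXIS)
        rres = standard_preprocess(rds, axis=ANALYSIS_AXIS)
        sec_items.append((sres.corrected, sres.mask))
        rep_items.append((rres.corrected, rres.mask))
    sec_cohort = build_cohort(sec_items)
    rep_cohort = build_cohort(rep_items)
    return {
        "spec": spec,
        "metadata": metadata,
        "sections": sec_cohort,
        "replicas": rep_cohort,
        "splits": make_splits(sec_cohort),
    }


def _matching_mean_spectra(fidelity: float, seed: int):
    spec = CohortSpec(n_patients=25, replica_fidelity=fidelity, seed=seed)
    sections, replicas, _meta = generate_cohort(spec)
    secs, reps, pairing = {}, {}, {}
    for (sds, _), (rds, _) in zip(sections, replicas):
        sres = standard_preprocess(sds, axis=ANALYSIS_AXIS)
        rres = standard_preprocess(rds, axis=ANALYSIS_AXIS)
        secs[sds.meta.sample_id] = mean_tissue_spectrum(sres.tic, sres.mask)
        reps[rds.meta.sample_id] = mean_tissue_spectrum(rres.tic, rres.mask)
        pairing[rds.meta.sample_id] = sds.meta.sample_id
    return secs, reps, pairing


@pytest.fixture(scope="session")
def matching_pairs():
    """25 section/replica mean-spectrum pairs at fidelity 1.0 and 0.9."""
    return {
        1.0: _matching_mean_spectra(1.0, seed=2),
        0.9: _matching_mean_spectra(0.9, seed=2),
    }


@pytest.fixture(scope="session")
def longitudinal_data():
    """Default longitudinal phantom: abundance series + planted effect tables."""
    spec = LongitudinalSpec(seed=0)
    datasets, tables = generate_longitudinal(spec)
    cells = {}
    for key, (ds, truth) in datasets.items():
        res = standard_preprocess(ds, axis=ANALYSIS_AXIS)
        labels = truth_region_labels(truth, ds.pixel_size)
        cells[key] = tumour_abundance(res.tic, labels, "T")
    series = build_series(cells)
    return {
        "spec": spec,
        "datasets": datasets,
        "tables": tables,
        "series": series,
        "axis": ANALYSIS_AXIS,
    }
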