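import numpy as np
import pytest

import progrnn as pg


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects, 20 genes, 8 clinical columns; deterministic."""
    cfg = pg.SimConfig(
        n_subjects=30, n_genes=20, n_clinical=8, n_signal_genes=4, seed=42
    )
    return cfg, pg.simulate_cohort(cfg)


@pytest.fixture()
def scaled_cohort(small_cohort):
    cfg, cohort = small_cohort
    cohort.scaling = pg.fit_scaling(cohort, cohort.subject_ids())
    return cfg, cohort


@pytest.fixture()
def tiny_model():
    """Smallest non-trivial architecture for fast structural tests."""
    config = pg.ModelConfig(
        cells_per_cb=4, cbs_per_db=2, n_dbs=2, seed=1, bn_epsilon=1e-3
    )
    return pg.DenseRNNRegressor(6, config)


def hand_cohort(visits_spec):
    """Build a minimal cohort from {sid: [(month, score), ...]} with two
    genes and one clinical column, feature values derived from the score."""
    subjects = {}
    for sid, visits in visits_spec.items():
        recs = []
        for month, score in visits:
            parts = (score, 0, 0, 0)
            recs.append(
                pg.VisitRecord(
                    subject_id=sid,
                    visit_month=float(month),
                    features=np.array([score + 1.0, 2.0, score / 10.0]),
                    score_parts=parts,
                    score_total=score,
                )
            )
        subjects[sid] = recs
    return pg.Cohort(
        subjects=subjects,
        gene_columns=["g1", "g2"],
        clinical_columns=["c1"],
    )
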