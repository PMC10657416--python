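import warnings

import numpy as np
import pytest

import dropgate as dg

# sklearn's LogisticRegressionCV emits FutureWarnings about upcoming API
# changes that are irrelevant to the computation
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_sim():
    """A reduced mixed simulation (3 types + debris + empties + dead cells)."""
    params = dg.SimParams(
        n_cell_types=3, cells_per_type=250, n_empty=8000, n_debris=80, seed=11
    )
    counts, ann, truth = dg.simulate_dataset(params)
    return counts, ann, truth


@pytest.fixture(scope="session")
def default_sim():
    """The bundled simulation at its default scale."""
    counts, ann, truth = dg.simulate_dataset(dg.SimParams(seed=1))
    return counts, ann, truth


@pytest.fixture(scope="session")
def staged_qc(default_sim):
    """Stages 1-3 run once on the default simulation, shared across tests."""
    counts, ann, truth = default_sim
    fit = dg.rank_threshold(counts.barcode_totals(), counts.barcode_ids)
    stage1 = dg.apply_rank_filter(counts, fit)
    qc = dg.compute_qc_metrics(stage1, ann)
    qc, mres = dg.run_stage2(qc, seed=1)
    qc, frame, de_results = dg.run_stage3(stage1, qc, seed=1)
    return {
        "counts": counts,
        "stage1": stage1,
        "qc": qc,
        "rank_fit": fit,
        "mito": mres,
        "frame": frame,
        "de_results": de_results,
        "truth": truth,
        "ann": ann,
    }


@pytest.fixture(scope="session")
def dead_result(staged_qc):
    """Dead-cell flagging on the default simulation, shared across tests."""
    return dg.flag_dead(staged_qc["stage1"], staged_qc["qc"], seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
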