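import numpy as np
import pytest

from irdl.features import log2_transform
from irdl.learner import LearnerConfig, run_increasing_learning
from irdl.pipeline import compute_feature_table
from irdl.synthetic import SyntheticConfig, generate_dataset


def prepare(ds):
    """Log2-transform expression and compute the per-pair feature table."""
    gene_log = log2_transform(ds.gene_expr_raw)
    lnc_log = log2_transform(ds.lnc_expr_raw)
    by_id = {f.id: f for f in ds.features}
    table = compute_feature_table(
        ds.pairs, by_id, ds.sequences, gene_log, lnc_log, ds.gene_open, ds.lnc_open
    )
    return table


def split_roles(ds):
    pos = [p for p in ds.pairs if p.role == "positive"]
    pool = [p for p in ds.pairs if p.role == "nearby_pool"]
    cands = [p for p in ds.pairs if p.role == "candidate"]
    return pos, pool, cands


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down dataset for fast structural checks."""
    cfg = SyntheticConfig(
        n_planted_positives=6, n_decoy_candidates=40, n_nearby_pool=120, seed=11
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """One full self-training run on the small dataset."""
    ds = small_dataset
    table = prepare(ds)
    pos, pool, cands = split_roles(ds)
    identified, state = run_increasing_learning(
        pos, pool, cands, table, LearnerConfig(), master_seed=11
    )
    return ds, table, identified, state


@pytest.fixture(scope="session")
def default_runs():
    """Self-training under the study conditions (defaults) across 5 seeds.

    Returns a list of (dataset, identified, state) triples.
    """
    out = []
    for seed in range(1, 6):
        ds = generate_dataset(SyntheticConfig(seed=seed))
        table = prepare(ds)
        pos, pool, cands = split_roles(ds)
        identified, state = run_increasing_learning(
            pos, pool, cands, table, LearnerConfig(), master_seed=seed
        )
        out.append((ds, identified, state))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(123)
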