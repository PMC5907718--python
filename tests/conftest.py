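import numpy as np
import pytest

from leafcall.cart import TrainConfig
from leafcall.evaluate import compare_to_truth, heldout_recall
from leafcall.pipeline import call_variants
from leafcall.simulate import SimConfig, simulate_dataset

# Desk-scale tree config: a few hundred candidates need proportionally
# smaller leaf floors than the whole-genome defaults or the tree cannot
# separate sequencing errors from real variants at all.
DESK_TRAIN = TrainConfig(min_leaf=10, min_split=20)


def run_end_to_end(tmp_dir, sim_config: SimConfig):
    """Simulate a dataset, run the caller on it, and evaluate against truth."""
    res = simulate_dataset(sim_config, tmp_dir)
    prefix = str(tmp_dir / "out")
    summary = call_variants(
        res["alignments"],
        res["known_vcf"],
        res["reference_dir"],
        prefix,
        train_config=DESK_TRAIN,
    )
    metrics = compare_to_truth(prefix + ".vcf", res["truth_vcf"])
    held = heldout_recall(prefix + ".vcf", res["heldout_tsv"]) if res["heldout"] else (float("nan"), 0)
    return {
        "sim": res,
        "summary": summary,
        "metrics": metrics,
        "heldout_recall": held[0],
        "n_heldout": held[1],
        "vcf": prefix + ".vcf",
        "tree": prefix + ".tree",
    }


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small (50 kb, 30x) simulated dataset for unit-level tests."""
    cfg = SimConfig(seed=11, genome_length=50_000, n_snv=50, n_ins=10, n_del=10, coverage=30.0, decoy_dbsnp=20)
    return simulate_dataset(cfg, tmp_path_factory.mktemp("small_sim"))


@pytest.fixture(scope="session")
def wgs_run(tmp_path_factory):
    """Full-conditions end-to-end run: 200 kb, 280 variants, 30x, complete database."""
    return run_end_to_end(tmp_path_factory.mktemp("wgs"), SimConfig(seed=1))


@pytest.fixture(scope="session")
def generalization_run(tmp_path_factory):
    """Same conditions with 10% of planted variants withheld from the database."""
    return run_end_to_end(tmp_path_factory.mktemp("gen"), SimConfig(seed=1, dbsnp_fraction=0.9))


@pytest.fixture(scope="session")
def lowcov_run(tmp_path_factory):
    """Low-pass variant of the same experiment: 4x coverage."""
    return run_end_to_end(tmp_path_factory.mktemp("lowcov"), SimConfig(seed=1, coverage=4.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
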