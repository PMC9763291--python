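"""Shared fixtures: synthetic study data prepared once per session."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import tcrpred as tp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Seed of the shared synthetic study; fixed so every run sees the same data.
STUDY_SEED = 11


@pytest.fixture(scope="session")
def gene_table():
    return tp.generate_gene_table(40, 10, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def synth(gene_table):
    """Default-condition synthetic study: (positives, background pool)."""
    config = tp.SynthConfig(seed=STUDY_SEED)
    positives, background = tp.generate_repertoire(config, gene_table)
    return {"config": config, "positives": positives, "background": background}


@pytest.fixture(scope="session")
def prepared(synth):
    """Redundancy-reduced, partitioned corpus with generated negatives."""
    reduced = tp.hobohm1_reduce(synth["positives"], 0.95)
    partitioned = tp.partition_data(
        reduced, tp.RedundancyConfig(seed=STUDY_SEED))
    build = tp.BuildConfig(min_positives_per_peptide=20, seed=STUDY_SEED)
    pool = synth["background"][:3000]
    corpus = tp.build_training_corpus(partitioned, pool, build)
    return {"reduced": partitioned, "corpus": corpus,
            "build": build, "background": synth["background"]}


@pytest.fixture(scope="session")
def small_records():
    """A handful of fully annotated records for cheap unit tests."""
    rng = np.random.default_rng(0)
    aa = list(tp.AMINO_ACIDS)
    recs = []
    for i in range(12):
        body_a = "".join(rng.choice(aa, size=9))
        body_b = "".join(rng.choice(aa, size=10))
        recs.append(tp.TCRRecord(
            cdr3a="C" + body_a + "F", cdr3b="C" + body_b + "F",
            peptide="GILGFVFTL" if i % 2 else "RAKFKQLL",
            cdr1a="TSGFYG", cdr2a="NALDGL", cdr1b="SGHTAL", cdr2b="FQGTGA",
            label=1, provenance="positive"))
    return tp.Repertoire(recs)
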