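"""Shared fixtures: one seeded synthetic dataset per session plus the
quantification products derived from it."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import pytest

from demethyl1 import annotations as ann
from demethyl1 import te_expression as texp
from demethyl1.simulate import Simulation, SimulationConfig

SEED = 42
CONDITIONS = ("control", "ko")
REPLICATES = (1, 2, 3)


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("simdata")
    Simulation(SimulationConfig(seed=SEED)).simulate_all(out)
    return out


@pytest.fixture(scope="session")
def sim(sim_dir) -> Simulation:
    s = Simulation(SimulationConfig(seed=SEED))
    s.simulate_genome_and_annotations()
    return s


@pytest.fixture(scope="session")
def truth(sim_dir) -> dict:
    with open(sim_dir / "truth.json") as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def te_fragments(sim_dir):
    return ann.parse_te_annotation(sim_dir / "te_annotation.bed")


@pytest.fixture(scope="session")
def transcripts(sim_dir):
    return ann.parse_gtf(sim_dir / "genes.gtf")


@pytest.fixture(scope="session")
def te_set(te_fragments, transcripts):
    """Exon-filtered TE set, as used for quantification."""
    return ann.filter_nonexonic(te_fragments, transcripts)


@pytest.fixture(scope="session")
def rna_sams(sim_dir) -> dict[str, Path]:
    return {
        f"{c}_{r}": sim_dir / f"rnaseq.{c}_{r}.sam"
        for c in CONDITIONS
        for r in REPLICATES
    }


@pytest.fixture(scope="session")
def groups(rna_sams) -> dict[str, str]:
    return {s: s.split("_")[0] for s in rna_sams}


@pytest.fixture(scope="session")
def te_matrix(rna_sams, te_set) -> texp.CountMatrix:
    return texp.quantify_samples(rna_sams, te_set, "reverse-stranded")


@pytest.fixture(scope="session")
def de_results(te_matrix, groups) -> pd.DataFrame:
    filtered = texp.filter_min_total(te_matrix)
    return texp.differential_test(
        filtered, groups, normalization="library-scaling", reference="control"
    )
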