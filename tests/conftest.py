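"""Shared fixtures.

The expensive session fixtures (30-taxon coevolution calibration, 24-taxon
codon engine, the tiny end-to-end pipeline runs) are built lazily, so fast
unit tests do not pay for them.
"""

from __future__ import annotations

import shutil
from pathlib import Path

import numpy as np
import pytest

from melcoev import coevolution as cv
from melcoev import selection as sel
from melcoev import synthetic_data as sd
from melcoev.pipeline import RunConfig, run_pipeline
from melcoev.seq_io import write_alignment
from melcoev.trees import Tree


@pytest.fixture
def quartet_tree() -> Tree:
    return Tree.from_newick("((A:0.2,B:0.3):0.1,(C:0.15,D:0.25):0.05);")


@pytest.fixture
def triplet_tree() -> Tree:
    return Tree.from_newick("(A:0.3,B:0.2,C:0.4);")


@pytest.fixture(scope="session")
def tree30() -> Tree:
    """30-taxon topology with uniform 0.1 branch lengths (the coevolution
    study-condition tree: deep divergence, every branch informative)."""
    base = sd.generate_tree(30, seed=101, height=0.5)
    return base.with_blen(np.where(base.parent >= 0, 0.1, 0.0))


@pytest.fixture(scope="session")
def coev_engine30(tree30) -> cv.CoevEngine:
    return cv.CoevEngine(tree30)


@pytest.fixture(scope="session")
def calibration30(tree30, coev_engine30) -> cv.NullCalibration:
    """Full dAIC null calibration: one 200-site JC69 alignment, all 19,900
    unordered site pairs."""
    return cv.calibrate_null(tree30, nsites=200, seed=42,
                             engine=coev_engine30)


@pytest.fixture(scope="session")
def tree24() -> Tree:
    """24-taxon topology with uniform 0.4 branch lengths (the selection
    study-condition tree: enough substitutions per branch for per-branch
    episode attribution)."""
    base = sd.generate_tree(24, seed=55, height=0.5)
    return base.with_blen(np.where(base.parent >= 0, 0.4, 0.0))


@pytest.fixture(scope="session")
def codon_engine24(tree24) -> sel.CodonEngine:
    return sel.CodonEngine(tree24, kappa=2.0)


def _tiny_scenario() -> sd.SyntheticScenario:
    return sd.SyntheticScenario(
        seed=11, n_taxa=12, tree_height=0.8,
        genes=[sd.GeneSpec("gA", 30, 1.0), sd.GeneSpec("gB", 24, 1.1),
               sd.GeneSpec("gC", 20, 0.9)],
        frac_positive=0.1, frac_neutral=0.1,
        planted_pairs=[
            sd.PlantedPair("gA", 5, "gB", 7, s=10.0, d=1.0,
                           profile=("AT", "GC")),
            sd.PlantedPair("gA", 12, "gC", 3, s=10.0, d=1.0,
                           profile=("AT", "GC")),
        ])


def _run_tiny_pipeline(root: Path, run_name: str) -> Path:
    data = root / "data"
    if not data.exists():
        data.mkdir(parents=True)
        alns, truth, tree = sd.generate_system(_tiny_scenario())
        for name, aln in alns.items():
            write_alignment(aln, data / f"{name}.fasta")
        tree.write(data / "species.nwk")
        sd.save_truth(truth, data / "truth.json")
    out = root / run_name
    cfg = RunConfig(
        gene_fastas={g: str(data / f"{g}.fasta") for g in ("gA", "gB", "gC")},
        tree_file=str(data / "species.nwk"),
        out_dir=str(out), null_pairs=800, null_nsites=120, seed=5)
    run_pipeline(cfg)
    return out


@pytest.fixture(scope="session")
def tiny_pipeline_runs(tmp_path_factory) -> tuple[Path, Path]:
    """The same small 3-gene system run through the full pipeline twice,
    into two separate output directories."""
    root = tmp_path_factory.mktemp("tinypipe")
    run1 = _run_tiny_pipeline(root, "run1")
    run2 = _run_tiny_pipeline(root, "run2")
    return run1, run2
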