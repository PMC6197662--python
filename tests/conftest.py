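"""Shared fixtures: the packaged strain table, stand-in features, and one
(cached) run of the full reproduction grid through the CLI."""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
import pytest

from xylact.dataio import load_fixture, write_feature_csv
from xylact.pseaac import extract_features
from xylact.synthetic import SimConfig, simulate_sequences

REPO_ROOT = Path(__file__).resolve().parents[1]

#: Where a user would drop the published supplementary feature spreadsheet
#: to enable the exact-reproduction checks against the printed tables.
S1_FEATURES_PATH = REPO_ROOT / "data" / "s1_pseaac_features.xlsx"

warnings.filterwarnings(
    "ignore", message="The least populated class", category=UserWarning
)


@pytest.fixture(scope="session")
def fixture_dataset():
    return load_fixture()


@pytest.fixture(scope="session")
def standin_features(fixture_dataset):
    """A synthetic stand-in feature matrix aligned to the fixture accessions.

    The real published feature matrix is not redistributable here; these
    rows are PseAAC vectors of random sequences and carry no information
    about the actual strains. They exercise shapes, alignment and plumbing.
    """
    seqs = simulate_sequences(SimConfig(n_sequences=41, seed=3))
    feats = extract_features(seqs)
    feats.index = pd.Index(fixture_dataset.accessions, name="id")
    return feats


@pytest.fixture(scope="session")
def cli_reproduction(tmp_path_factory, standin_features):
    """One CLI `reproduce` run on fixture + stand-in features (shared: the
    full model x scheme x condition grid takes ~10 s)."""
    from click.testing import CliRunner
    from xylact.cli import main

    outdir = tmp_path_factory.mktemp("reproduction")
    feat_csv = outdir / "features.csv"
    write_feature_csv(standin_features, feat_csv)
    prefix = outdir / "repro"
    result = CliRunner().invoke(
        main, ["reproduce", "--features", str(feat_csv), "--seed", "3",
               "--out-prefix", str(prefix)],
    )
    assert result.exit_code == 0, result.output
    return {
        "classification": prefix.parent / "repro_classification.csv",
        "regression": prefix.parent / "repro_regression.csv",
        "report": prefix.parent / "repro_report.txt",
    }
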