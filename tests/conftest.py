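from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from taxonscrub import (Checklist, ColumnMapping, Config, FixtureSpec,
                        TaxonRecord, generate_checklist, load_checklist,
                        read_occurrences, uropygi_example)

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


def make_checklist(entries, source_id=11) -> Checklist:
    """Build an in-memory checklist from (taxon_id, name, rank) triples."""
    from taxonscrub.nameparse import parse_scientific_name
    records = [
        TaxonRecord(taxon_id=tid, source_id=source_id, scientific_name=name,
                    canonical_name=parse_scientific_name(name).canonical,
                    rank=rank)
        for tid, name, rank in entries
    ]
    return Checklist(records=records, source_id=source_id)


@pytest.fixture(scope="session")
def worked_example(tmp_path_factory):
    return uropygi_example(tmp_path_factory.mktemp("uropygi"))


@pytest.fixture(scope="session")
def worked_checklist(worked_example):
    return load_checklist(worked_example.checklist_path, 11)


@pytest.fixture(scope="session")
def worked_table(worked_example):
    return read_occurrences(worked_example.occurrences_path,
                            ColumnMapping.identity())


@pytest.fixture(scope="session")
def random_checklist(tmp_path_factory):
    """A mid-sized synthetic checklist with no separation constraint."""
    d = tmp_path_factory.mktemp("randcl")
    spec = FixtureSpec(n_lineages=60, min_pairwise_distance=1, seed=7)
    path = generate_checklist(spec, d / "checklist.csv")
    return load_checklist(path, 11)


@pytest.fixture()
def default_config():
    return Config()


def write_csv(path: Path, text: str) -> Path:
    path.write_text(text, encoding="utf-8")
    return path
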