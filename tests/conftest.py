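from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from disptm.io import DisorderProfile, ProteinRecord


def rec(pid: str, seq: str, **kw) -> ProteinRecord:
    return ProteinRecord(pid, seq, **kw)


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write raw FASTA text to a temp file and return the path."""

    def _write(text: str, name: str = "in.fasta") -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def write_tsv(tmp_path):
    def _write(text: str, name: str = "table.tsv") -> Path:
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write


@pytest.fixture
def tiny_proteome():
    """Three proteins with hand-checkable disorder masks."""
    records = [
        rec("p1", "MSSPKRTYAG"),
        rec("p2", "AAAAAAAAAA"),
        rec("p3", "KRKRKRKRKR"),
    ]
    profiles = [
        DisorderProfile("p1", np.array([1, 1, 1, 0, 0, 0, 0, 0, 1, 1], bool)),
        DisorderProfile("p2", np.zeros(10, bool)),
        DisorderProfile("p3", np.ones(10, bool)),
    ]
    return records, profiles
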