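from pathlib import Path

import pytest

from shspkit.sequences import SequenceRecord, write_fasta


@pytest.fixture
def fasta_file(tmp_path):
    """Write records (or raw (id, seq) pairs) to a temporary FASTA and
    return the path."""

    def _write(records, name="seqs.fasta"):
        recs = [
            r if isinstance(r, SequenceRecord) else SequenceRecord(id=r[0], seq=r[1])
            for r in records
        ]
        path = tmp_path / name
        write_fasta(recs, path)
        return path

    return _write


#: Repository-level directory for user-supplied reference sequences.
REFERENCE_DIR = Path(__file__).resolve().parent.parent / "data" / "reference"
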