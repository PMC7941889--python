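import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cmline.io_formats import Alignment, SeqRecord

MINIMAL_STOCKHOLM = """\
# STOCKHOLM 1.0
#=GF ID minimal
#=GS human/1-6 OS Homo sapiens
human/1-6 ACGUAC
mouse/1-6 ACGUAC
#=GC SS_cons <<..>>
//
"""

TOY_GFF = """\
##gff-version 3
chr1\ttest\tgene\t101\t400\t.\t+\t.\tID=gene1
chr1\ttest\tmRNA\t101\t400\t.\t+\t.\tID=t1;Parent=gene1
chr1\ttest\texon\t101\t200\t.\t+\t.\tID=e1;Parent=t1
chr1\ttest\texon\t301\t400\t.\t+\t.\tID=e2;Parent=t1
"""


@pytest.fixture
def minimal_stockholm(tmp_path):
    path = tmp_path / "minimal.sto"
    path.write_text(MINIMAL_STOCKHOLM)
    return path


@pytest.fixture
def toy_gff(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF)
    return path


def make_alignment(rows: list[str], ss: str, ids=None, species=None) -> Alignment:
    records = []
    for k, residues in enumerate(rows):
        rid = ids[k] if ids else f"sp{k + 1:04d}/1-{len(residues)}"
        sp = species[k] if species else rid.split("/")[0]
        records.append(SeqRecord(rid, residues, species=sp))
    return Alignment(records, ss)
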