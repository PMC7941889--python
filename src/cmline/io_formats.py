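"""Readers and writers for the formats the pipeline consumes and emits.

Stockholm 1.0 alignments (with ``#=GC SS_cons`` consensus structure and
``#=GS ... OS`` organism annotations), FASTA (soft-masking preserved as a
boolean track), GFF3 features, BLAST tabular (outfmt 6) pairwise-hit files,
and BED6 region output.  WUSS consensus-structure strings are parsed into
explicit base-pair tables.

Internal conventions: residues are normalized to uppercase RNA (T -> U) at
read time; coordinates are 0-based half-open everywhere inside the package
and converted to/from the 1-based closed convention only at the GFF3/BED
boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "CmlineError",
    "StockholmError",
    "WussError",
    "SeqRecord",
    "Alignment",
    "PairTable",
    "Feature",
    "PairwiseHit",
    "read_stockholm",
    "write_stockholm",
    "parse_wuss",
    "pairs_to_wuss",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "read_hits_table",
    "write_hits_table",
    "write_bed",
]


class CmlineError(Exception):
    """Base class for structured errors raised by this package."""


class StockholmError(CmlineError):
    pass


class WussError(CmlineError):
    pass


_RNA_CANONICAL = frozenset("ACGU")


def normalize_residues(raw: str) -> tuple[str, tuple[bool, ...]]:
    """Uppercase, DNA->RNA (T->U). Returns (residues, masked track).

    The masked track records which positions were lowercase (soft-masked)
    in the input; residues themselves carry a single alphabet so that
    pairing logic never has to reason about case.
    """
    masked = tuple(c.islower() for c in raw)
    residues = raw.upper().replace("T", "U")
    return residues, masked


@dataclass
class SeqRecord:
    """A (possibly aligned) sequence with optional species label.

    ``residues`` are uppercase RNA plus gaps/ambiguity codes; ``masked`` is
    a parallel soft-masking track (True where the source was lowercase).
    """

    id: str
    residues: str
    species: str = ""
    masked: tuple[bool, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CmlineError("SeqRecord id must be non-empty")
        if not self.residues:
            raise CmlineError(f"SeqRecord {self.id!r} has empty residues")
        if self.masked is not None and len(self.masked) != len(self.residues):
            raise CmlineError(f"masked track length mismatch for {self.id!r}")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "").replace(".", "")


def species_from_id(identifier: str) -> str:
    """Default species label: id prefix before the first '/' or whitespace."""
    return re.split(r"[/\s]", identifier, maxsplit=1)[0]


@dataclass
class Alignment:
    """Rows + WUSS consensus structure + free-form metadata.

    Duplicate sequences are permitted (identical homologs from different
    species are deliberately kept when counting representatives).
    """

    rows: list[SeqRecord]
    ss_cons: str
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.rows:
            raise CmlineError("Alignment needs at least one row")
        width = len(self.rows[0].residues)
        for row in self.rows:
            if len(row.residues) != width:
                raise StockholmError(
                    f"ragged alignment: row {row.id!r} has length "
                    f"{len(row.residues)}, expected {width}"
                )
        if len(self.ss_cons) != width:
            raise StockholmError(
                f"SS_cons length {len(self.ss_cons)} != alignment width {width}"
            )

    @property
    def width(self) -> int:
        return len(self.ss_cons)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def species(self) -> list[str]:
        return [r.species or species_from_id(r.id) for r in self.rows]

    def n_species(self) -> int:
        return len(set(self.species()))

    def columns(self, i: int) -> str:
        return "".join(r.residues[i] for r in self.rows)


# ---------------------------------------------------------------------------
# WUSS consensus structure
# ---------------------------------------------------------------------------

_OPEN = {"<": ">", "(": ")", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}
_PK_OPEN = "ABCD"
_PK_CLOSE = "abcd"
_UNPAIRED = set(".,:_-~")


@dataclass
class PairTable:
    """Base pairs (i, j) with i < j, 0-based, plus per-pair nesting layer.

    Layer 0 is the nested backbone; layers >= 1 are pseudoknot letters
    (A=1 ... D=4).  Each column index occurs in at most one pair.
    """

    pairs: list[tuple[int, int]]
    layer: list[int]
    length: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise WussError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise WussError(f"column in more than one pair: ({i},{j})")
            seen.update((i, j))
        if len(self.layer) != len(self.pairs):
            raise WussError("layer list must parallel pairs")

    def layer0(self) -> list[tuple[int, int]]:
        return [p for p, l in zip(self.pairs, self.layer) if l == 0]

    def pseudoknot(self) -> list[tuple[int, int]]:
        return [p for p, l in zip(self.pairs, self.layer) if l > 0]

    @property
    def has_pseudoknot(self) -> bool:
        return any(l > 0 for l in self.layer)


def parse_wuss(ss: str) -> PairTable:
    """Parse a WUSS consensus-structure string into a pair table.

    Bracket classes <>, (), [], {} all map to the nested layer 0; the
    pseudoknot letters Aa..Dd map to layers 1..4.  Unmatched openers or
    closers raise :class:`WussError` naming the offending column.
    """
    stacks: dict[str, list[int]] = {b: [] for b in _OPEN}
    pk_stacks: dict[str, list[int]] = {c: [] for c in _PK_OPEN}
    pairs: list[tuple[int, int]] = []
    layers: list[int] = []
    for col, ch in enumerate(ss):
        if ch in _OPEN:
            stacks[ch].append(col)
        elif ch in _CLOSE:
            opener = _CLOSE[ch]
            if not stacks[opener]:
                raise WussError(f"unbalanced {ch!r} at column {col}")
            pairs.append((stacks[opener].pop(), col))
            layers.append(0)
        elif ch in _PK_OPEN:
            pk_stacks[ch].append(col)
        elif ch in _PK_CLOSE:
            upper = ch.upper()
            if not pk_stacks[upper]:
                raise WussError(f"unbalanced pseudoknot {ch!r} at column {col}")
            pairs.append((pk_stacks[upper].pop(), col))
            layers.append(_PK_OPEN.index(upper) + 1)
        elif ch in _UNPAIRED:
            continue
        else:
            raise WussError(f"invalid WUSS character {ch!r} at column {col}")
    for bracket, stack in stacks.items():
        if stack:
            raise WussError(f"unmatched {bracket!r} opened at column {stack[-1]}")
    for letter, stack in pk_stacks.items():
        if stack:
            raise WussError(f"unmatched pseudoknot {letter!r} opened at column {stack[-1]}")
    order = sorted(range(len(pairs)), key=lambda k: pairs[k])
    return PairTable([pairs[k] for k in order], [layers[k] for k in order], len(ss))


def pairs_to_wuss(pt: PairTable) -> str:
    """Serialize a pair table back to WUSS ('<>' for layer 0, letters above)."""
    out = ["."] * pt.length
    for (i, j), layer in zip(pt.pairs, pt.layer):
        if layer == 0:
            out[i], out[j] = "<", ">"
        else:
            out[i] = _PK_OPEN[layer - 1]
            out[j] = _PK_CLOSE[layer - 1]
    return "".join(out)


# ---------------------------------------------------------------------------
# Stockholm
# ---------------------------------------------------------------------------

_GF_SKIP = {"SQ"}  # writer-managed bookkeeping lines


def _scan_gf_lines(text: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in text.splitlines():
        m = re.match(r"#=GF\s+(\S+)\s+(.*)$", line)
        if m and m.group(1) not in _GF_SKIP:
            key, value = m.group(1), m.group(2).strip()
            meta[key] = f"{meta[key]} {value}" if key in meta else value
    return meta


def read_stockholm(path: str | Path) -> Alignment:
    """Read a single-block Stockholm alignment with a consensus structure.

    Species labels come from ``#=GS ... OS`` organism annotations when
    present, otherwise from the row-id prefix before '/'; header-level
    ``#=GF`` annotations (where some files keep their species list) are
    captured verbatim into ``Alignment.metadata``.
    """
    text = Path(path).read_text()
    try:
        bio_aln = AlignIO.read(StringIO(text), "stockholm")
    except ValueError as exc:
        raise StockholmError(f"cannot parse {path}: {exc}") from exc
    ss_cons = bio_aln.column_annotations.get("secondary_structure")
    if ss_cons is None:
        raise StockholmError(f"{path}: no consensus structure (#=GC SS_cons line)")
    rows = []
    for rec in bio_aln:
        residues, masked = normalize_residues(str(rec.seq))
        species = rec.annotations.get("organism", "") or species_from_id(rec.id)
        rows.append(SeqRecord(rec.id, residues, species=species, masked=masked))
    return Alignment(rows, ss_cons, metadata=_scan_gf_lines(text))


def write_stockholm(aln: Alignment, path: str | Path) -> None:
    """Write Stockholm 1.0; read_stockholm(write_stockholm(a)) == a."""
    lines = ["# STOCKHOLM 1.0"]
    for key, value in aln.metadata.items():
        lines.append(f"#=GF {key} {value}")
    name_w = max(len(r.id) for r in aln.rows)
    name_w = max(name_w, len("#=GC SS_cons") - len("#=GS  OS"))
    for row in aln.rows:
        if row.species and row.species != species_from_id(row.id):
            lines.append(f"#=GS {row.id} OS {row.species}")
    for row in aln.rows:
        lines.append(f"{row.id:<{name_w}} {row.residues}")
    lines.append(f"{'#=GC SS_cons':<{name_w}} {aln.ss_cons}")
    lines.append("//")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SeqRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues, masked = normalize_residues(str(rec.seq))
        records.append(SeqRecord(rec.id, residues, masked=masked))
    return records


def write_fasta(records: list[SeqRecord], path: str | Path) -> None:
    """Write FASTA, re-applying soft-masking (lowercase) from the mask track."""
    bio_records = []
    for rec in records:
        if rec.masked is not None and any(rec.masked):
            seq = "".join(
                c.lower() if m else c for c, m in zip(rec.residues, rec.masked)
            )
        else:
            seq = rec.residues
        bio_records.append(_BioSeqRecord(Seq(seq), id=rec.id, description=""))
    SeqIO.write(bio_records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    """One GFF3 feature, coordinates exactly as read (1-based closed)."""

    seqid: str
    type: str
    start: int
    end: int
    strand: str
    attrs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CmlineError(
                f"invalid feature coordinates {self.start}..{self.end} on {self.seqid}"
            )
        if self.strand not in {"+", "-", "."}:
            raise CmlineError(f"invalid strand {self.strand!r}")

    @property
    def id(self) -> str:
        return self.attrs.get("ID", "")

    @property
    def parent(self) -> str:
        return self.attrs.get("Parent", "")


def read_gff(path: str | Path) -> list[Feature]:
    """Read GFF3 into a flat feature list (gffutils in-memory DB underneath)."""
    import gffutils

    text = Path(path).read_text()
    if not text.strip():
        return []
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    features = []
    for f in db.all_features(order_by=("seqid", "start")):
        attrs = {k: ",".join(v) for k, v in f.attributes.items()}
        features.append(
            Feature(f.seqid, f.featuretype, f.start, f.end, f.strand or ".", attrs)
        )
    return features


# ---------------------------------------------------------------------------
# Pairwise hits (BLAST outfmt-6 dialect)
# ---------------------------------------------------------------------------

@dataclass
class PairwiseHit:
    """One row of a 12-column tabular hit file."""

    query: str
    subject: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise CmlineError(f"negative E-value {self.evalue} for {self.query}/{self.subject}")


def read_hits_table(path: str | Path) -> list[PairwiseHit]:
    """Parse tabular (outfmt 6) hits; malformed lines reported by number."""
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise CmlineError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            try:
                hits.append(
                    PairwiseHit(
                        query=parts[0],
                        subject=parts[1],
                        pident=float(parts[2]),
                        length=int(parts[3]),
                        mismatch=int(parts[4]),
                        gapopen=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        score=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise CmlineError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits_table(hits: list[PairwiseHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.pident:.1f}\t{h.length}\t{h.mismatch}\t"
                f"{h.gapopen}\t{h.qstart}\t{h.qend}\t{h.sstart}\t{h.send}\t"
                f"{h.evalue:.2g}\t{h.score:g}\n"
            )


def write_bed(regions, path: str | Path) -> None:
    """BED6 output for Region-like objects (0-based half-open already)."""
    with open(path, "w") as fh:
        for r in regions:
            name = getattr(r, "provenance", "") or getattr(r, "kind", ".") or "."
            fh.write(f"{r.seqid}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")
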