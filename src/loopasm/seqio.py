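"""DNA record model with strand/topology semantics and GenBank/FASTA I/O.

Coordinates are 0-based half-open everywhere inside the package; they are
converted to 1-based inclusive only when talking to GenBank.  Circular
molecules are stored unwrapped; a feature that crosses the origin keeps
``start < len(sequence) <= end`` (the "wrapped span" convention).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

__all__ = [
    "DnaMolecule",
    "Feature",
    "FEATURE_KINDS",
    "reverse_complement",
    "canonical_rotation",
    "translate_cds",
    "load_record",
    "load_records",
    "save_record",
    "records_equal",
]

DNA_ALPHABET = set("ACGTN")

FEATURE_KINDS = frozenset(
    {
        "promoter",
        "CDS",
        "terminator",
        "tag",
        "RBS",
        "marker",
        "dropout",
        "recognition_site",
        "UNS",
        "scar",
        "other",
    }
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SeqIoError(ValueError):
    """Raised for malformed records or malformed format payloads."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``."""
    _check_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SeqIoError(f"sequence contains non-IUPAC residues: {sorted(bad)}")


@dataclasses.dataclass
class Feature:
    """A located annotation on a :class:`DnaMolecule`.

    ``start``/``end`` form a 0-based half-open interval.  On circular
    molecules the span may wrap: ``start < L <= end`` with ``end - start``
    the true feature length.
    """

    kind: str
    label: str
    start: int
    end: int
    strand: int = 1
    qualifiers: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise SeqIoError(f"unknown feature kind {self.kind!r}")
        if self.end <= self.start:
            raise SeqIoError(
                f"feature {self.label!r}: span end must exceed start "
                f"({self.start}, {self.end})"
            )
        if self.strand not in (1, -1):
            raise SeqIoError("feature strand must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def shifted(self, offset: int) -> "Feature":
        return dataclasses.replace(
            self, start=self.start + offset, end=self.end + offset
        )


@dataclasses.dataclass
class DnaMolecule:
    """An annotated linear or circular double-stranded DNA record."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list = dataclasses.field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SeqIoError(f"molecule {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        _check_alphabet(self.sequence)
        if self.topology not in ("circular", "linear"):
            raise SeqIoError(f"unknown topology {self.topology!r}")
        for feat in self.features:
            self._check_feature(feat)

    def _check_feature(self, feat: Feature) -> None:
        L = len(self.sequence)
        if feat.end > L:
            if self.topology != "circular":
                raise SeqIoError(
                    f"wrapped feature {feat.label!r} on linear molecule {self.id!r}"
                )
            if feat.start >= L or feat.length > L:
                raise SeqIoError(f"feature {feat.label!r} span out of range")
        if (
            feat.kind == "CDS"
            and feat.length % 3
            and not feat.qualifiers.get("partial")
        ):
            raise SeqIoError(
                f"CDS feature {feat.label!r} length {feat.length} not divisible "
                "by 3 (set qualifier partial=True to override)"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def add_feature(self, feat: Feature) -> None:
        self._check_feature(feat)
        self.features.append(feat)

    def region(self, start: int, end: int) -> str:
        """Wrap-aware subsequence (end may exceed the length on circles)."""
        L = len(self.sequence)
        if end <= L:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise SeqIoError("wrapped region on linear molecule")
        return self.sequence[start:] + self.sequence[: end - L]


def _least_rotation(s: str) -> int:
    """Index of the lexicographically least rotation (Booth's algorithm)."""
    s2 = s + s
    f = [-1] * len(s2)
    k = 0
    for j in range(1, len(s2)):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonical_rotation(mol: "DnaMolecule | str") -> str:
    """Canonical string form of a circular sequence.

    The lexicographically smallest string among all rotations of the
    sequence and all rotations of its reverse complement.  Two circular
    molecules are the same plasmid iff their canonical forms match.
    """
    if isinstance(mol, DnaMolecule):
        if mol.topology != "circular":
            raise SeqIoError("canonical_rotation requires a circular molecule")
        seq = mol.sequence
    else:
        seq = mol
    rc = reverse_complement(seq)
    k1 = _least_rotation(seq)
    k2 = _least_rotation(rc)
    return min(seq[k1:] + seq[:k1], rc[k2:] + rc[:k2])


def translate_cds(seq: str) -> str:
    """Translate with the standard genetic code; stops render as ``*``."""
    _check_alphabet(seq)
    if len(seq) % 3:
        raise SeqIoError(f"CDS length {len(seq)} not divisible by 3")
    return str(Seq(seq).translate(table=1))


# ---------------------------------------------------------------------------
# GenBank / FASTA conversion


def _feature_to_seqfeature(feat: Feature, length: int) -> SeqFeature:
    if feat.end > length:  # wrapped on a circular molecule
        loc = CompoundLocation(
            [
                SimpleLocation(feat.start, length, strand=feat.strand),
                SimpleLocation(0, feat.end - length, strand=feat.strand),
            ]
        )
    else:
        loc = SimpleLocation(feat.start, feat.end, strand=feat.strand)
    ftype = feat.kind if feat.kind in ("CDS", "promoter", "terminator", "RBS") else "misc_feature"
    quals = {"label": [feat.label], "loopasm_kind": [feat.kind]}
    for key, val in feat.qualifiers.items():
        quals[key] = [str(val)]
    return SeqFeature(loc, type=ftype, qualifiers=quals)


def _seqfeature_to_feature(sf: SeqFeature, length: int) -> Feature | None:
    if sf.location is None:
        return None
    parts = sorted(sf.location.parts, key=lambda p: int(p.start))
    start = int(parts[0].start)
    end = int(parts[-1].end)
    if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == length:
        # origin-spanning compound location stored as (x..L, 0..y)
        start = int(parts[1].start)
        end = length + int(parts[0].end)
    strand = sf.location.strand or 1
    quals = {k: v[0] if isinstance(v, list) and v else v for k, v in sf.qualifiers.items()}
    kind = quals.pop("loopasm_kind", None)
    if kind not in FEATURE_KINDS:
        kind = sf.type if sf.type in FEATURE_KINDS else "other"
    label = quals.pop("label", None) or quals.get("gene") or quals.get("note") or sf.type
    if kind == "CDS" and (end - start) % 3:
        quals.setdefault("partial", "true")
    return Feature(kind=kind, label=str(label), start=start, end=end, strand=strand, qualifiers=quals)


def _to_seqrecord(mol: DnaMolecule) -> SeqRecord:
    for feat in mol.features:
        if feat.end > len(mol) and mol.topology != "circular":
            raise SeqIoError(f"wrapped feature {feat.label!r} on linear molecule")
    rec = SeqRecord(Seq(mol.sequence), id=mol.id, name=mol.id[:16], description=mol.provenance)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = mol.topology
    rec.features = [_feature_to_seqfeature(f, len(mol)) for f in mol.features]
    return rec


def _from_seqrecord(rec: SeqRecord) -> DnaMolecule:
    topology = rec.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    feats = []
    for sf in rec.features:
        if sf.type == "source":
            continue
        feat = _seqfeature_to_feature(sf, len(rec.seq))
        if feat is not None:
            feats.append(feat)
    return DnaMolecule(
        id=rec.id,
        sequence=str(rec.seq).upper(),
        topology=topology,
        features=feats,
        provenance=rec.description if rec.description != "<unknown description>" else "",
    )


def load_records(path, fmt: str | None = None) -> list[DnaMolecule]:
    """Load every record from a GenBank or FASTA file."""
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    if fmt not in ("genbank", "fasta"):
        raise SeqIoError(f"unsupported format {fmt!r}")
    try:
        recs = list(SeqIO.parse(str(path), fmt))
    except ValueError as exc:
        raise SeqIoError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not recs:
        raise SeqIoError(f"no records found in {path}")
    mols = [_from_seqrecord(r) for r in recs]
    ids = [m.id for m in mols]
    if len(set(ids)) != len(ids):
        raise SeqIoError(f"duplicate record ids in {path}")
    return mols


def load_record(path, fmt: str | None = None) -> DnaMolecule:
    """Load a single record; error if the file holds more than one."""
    mols = load_records(path, fmt)
    if len(mols) != 1:
        raise SeqIoError(f"expected one record in {path}, found {len(mols)}")
    return mols[0]


def save_record(mol: DnaMolecule, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    if fmt not in ("genbank", "fasta"):
        raise SeqIoError(f"unsupported format {fmt!r}")
    SeqIO.write([_to_seqrecord(mol)], str(path), fmt)


def save_records(mols: Iterable[DnaMolecule], path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta"
    SeqIO.write([_to_seqrecord(m) for m in mols], str(path), fmt)


def records_equal(a: DnaMolecule, b: DnaMolecule) -> bool:
    """Topology-aware sequence identity (rotation/reflection for circles)."""
    if a.topology != b.topology:
        return False
    if a.topology == "circular":
        return canonical_rotation(a) == canonical_rotation(b)
    return a.sequence == b.sequence or a.sequence == reverse_complement(b.sequence)
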