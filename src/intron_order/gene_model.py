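"""Gene models with typed introns, primers, and trans-spliced 5' ends.

A gene is represented in transcript orientation as one pre-mRNA sequence
tiled, without gaps or overlaps, by an optional outron (the 5' semi-intron
replaced by the splice leader during trans-splicing), exons, and introns.
Every intron carries an operational category — ``conventional``
(spliceosomal) or ``nonconventional`` (euglenozoan-specific, secondary-
structure mediated) — plus an ``intermediate`` flag for introns showing
features of both types.  Intermediate introns are resolved to one category
in the annotation itself: the category drives all downstream logic, the
flag is bookkeeping.

Coordinates are 0-based half-open throughout; GFF3 I/O converts to/from the
1-based closed convention of that format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONVENTIONAL = "conventional"
NONCONVENTIONAL = "nonconventional"

_CATEGORIES = frozenset({CONVENTIONAL, NONCONVENTIONAL})
_MIN_INTRON_LENGTH = 4


class GeneModelError(ValueError):
    """Structural problem in a gene model (tiling, ordering, ranges)."""


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class IntronAnnotation:
    """One intron: 1-based ordinal, half-open interval, resolved category."""

    ordinal: int
    start: int
    end: int
    category: str
    intermediate: bool = False

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise GeneModelError(f"intron ordinal must be >= 1, got {self.ordinal}")
        if not self.start < self.end:
            raise GeneModelError(
                f"intron {self.ordinal}: start {self.start} must be < end {self.end}"
            )
        if self.length < _MIN_INTRON_LENGTH:
            raise GeneModelError(
                f"intron {self.ordinal}: length {self.length} < {_MIN_INTRON_LENGTH}"
            )
        if self.category not in _CATEGORIES:
            raise GeneModelError(f"unknown intron category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A single-isoform gene in transcript orientation.

    ``exons`` and ``introns`` (plus ``outron``, if any) must tile
    ``sequence`` exactly.  ``splice_leader`` is the short sequence added to
    the transcript 5' end in place of the outron by trans-splicing; it is
    not part of ``sequence``.
    """

    name: str
    sequence: str
    exons: list[tuple[int, int]]
    introns: list[IntronAnnotation]
    outron: Optional[tuple[int, int]] = None
    splice_leader: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.splice_leader is not None:
            self.splice_leader = self.splice_leader.upper()
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.sequence)
        pieces: list[tuple[int, int, str]] = []
        if self.outron is not None:
            if self.outron[0] != 0:
                raise GeneModelError("outron must start at position 0")
            if self.splice_leader is None:
                raise GeneModelError("a model with an outron needs a splice leader")
            pieces.append((*self.outron, "outron"))
        elif self.splice_leader is not None:
            raise GeneModelError("splice leader given but no outron annotated")
        for i, (s, e) in enumerate(self.exons, start=1):
            pieces.append((s, e, f"exon {i}"))
        for iv in self.introns:
            pieces.append((iv.start, iv.end, f"intron {iv.ordinal}"))

        ordinals = [iv.ordinal for iv in self.introns]
        if ordinals != sorted(ordinals) or len(set(ordinals)) != len(ordinals):
            raise GeneModelError("intron ordinals must be unique and ascending")
        starts = [iv.start for iv in self.introns]
        if starts != sorted(starts):
            raise GeneModelError("intron ordinals must follow 5'->3' order")

        pieces.sort()
        cursor = 0
        for s, e, label in pieces:
            if s < 0 or e > n:
                raise GeneModelError(f"{label} [{s},{e}) outside sequence of length {n}")
            if s < cursor:
                raise GeneModelError(f"{label} overlaps the preceding feature")
            if s > cursor:
                raise GeneModelError(f"gap before {label}: [{cursor},{s}) unannotated")
            cursor = e
        if cursor != n:
            raise GeneModelError(f"features end at {cursor}, sequence length is {n}")

    # -- accessors --------------------------------------------------------

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    def intron(self, ordinal: int) -> IntronAnnotation:
        for iv in self.introns:
            if iv.ordinal == ordinal:
                return iv
        raise KeyError(f"no intron with ordinal {ordinal} in {self.name}")

    def intron_categories(self) -> dict[int, str]:
        return {iv.ordinal: iv.category for iv in self.introns}

    def mature_sequence(self) -> str:
        """Exon concatenation, with the splice leader prepended if trans-spliced."""
        body = "".join(self.sequence[s:e] for s, e in self.exons)
        if self.splice_leader is not None:
            return self.splice_leader + body
        return body


@dataclass(frozen=True)
class Primer:
    """A PCR/RT primer written 5'->3', anchored to one gene feature.

    ``anchor`` is ``(feature_kind, ordinal, offset)``: the primer site starts
    ``offset`` nt into the feature on the sense strand.  Forward primers
    equal the sense-strand site; reverse primers are its reverse complement.
    """

    name: str
    sequence: str
    orientation: str
    anchor: tuple[str, int, int]

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad primer orientation {self.orientation!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def site(self) -> str:
        """The sense-strand sequence this primer anneals over."""
        if self.orientation == "forward":
            return self.sequence
        return reverse_complement(self.sequence)


def feature_sequence(model: GeneModel, feature_kind: str, ordinal: int = 1) -> str:
    """Return the sense-strand sequence of one annotated feature."""
    if feature_kind == "exon":
        try:
            s, e = model.exons[ordinal - 1]
        except IndexError:
            raise KeyError(f"no exon {ordinal} in {model.name}") from None
        if ordinal < 1:
            raise KeyError(f"no exon {ordinal} in {model.name}")
        return model.sequence[s:e]
    if feature_kind == "intron":
        iv = model.intron(ordinal)
        return model.sequence[iv.start : iv.end]
    if feature_kind == "outron":
        if model.outron is None:
            raise KeyError(f"{model.name} has no outron")
        s, e = model.outron
        return model.sequence[s:e]
    if feature_kind == "splice_leader":
        if model.splice_leader is None:
            raise KeyError(f"{model.name} has no splice leader")
        return model.splice_leader
    raise KeyError(f"unknown feature kind {feature_kind!r}")


def design_primer(
    model: GeneModel,
    name: str,
    orientation: str,
    feature_kind: str,
    ordinal: int,
    offset: int,
    length: int = 20,
) -> Primer:
    """Cut a primer of ``length`` nt out of a feature at ``offset``.

    ``offset < 0`` counts from the feature 3' end (``-length`` puts the
    site flush with the feature end).
    """
    feat = feature_sequence(model, feature_kind, ordinal)
    if offset < 0:
        offset += len(feat)
    site = feat[offset : offset + length]
    if len(site) != length:
        raise ValueError(
            f"primer {name}: site [{offset},{offset+length}) exceeds "
            f"{feature_kind} {ordinal} (length {len(feat)})"
        )
    seq = site if orientation == "forward" else reverse_complement(site)
    return Primer(name, seq, orientation, (feature_kind, ordinal, offset))


def validate_primer(model: GeneModel, primer: Primer) -> None:
    """Check that the primer matches the gene model exactly at its anchor."""
    kind, ordinal, offset = primer.anchor
    feat = feature_sequence(model, kind, ordinal)
    site = feat[offset : offset + len(primer.sequence)]
    if site != primer.site:
        raise GeneModelError(
            f"primer {primer.name} does not match {model.name} at "
            f"{kind} {ordinal} offset {offset}"
        )


# ---------------------------------------------------------------------------
# I/O: FASTA + (GFF3 | TSV) for gene models, TSV for primers
# ---------------------------------------------------------------------------

_SL_PRAGMA = "#!splice_leader="


def write_gene_model(model: GeneModel, fasta_path: str, gff3_path: str) -> None:
    """Write the pre-mRNA FASTA and a GFF3 annotation.

    Feature types are ``exon``, ``intron`` and ``outron``; introns carry
    ``intron_category`` and ``intermediate`` attributes.  The splice leader,
    which has no coordinates on the pre-mRNA, is stored in a
    ``#!splice_leader=`` header line.
    """
    rec = SeqRecord(Seq(model.sequence), id=model.name, description="")
    SeqIO.write([rec], fasta_path, "fasta")
    lines = ["##gff-version 3"]
    if model.splice_leader is not None:
        lines.append(_SL_PRAGMA + model.splice_leader)
    def row(ftype: str, s: int, e: int, attrs: str) -> str:
        return "\t".join(
            [model.name, "intron_order", ftype, str(s + 1), str(e), ".", "+", ".", attrs]
        )
    if model.outron is not None:
        lines.append(row("outron", *model.outron, f"ID={model.name}:outron"))
    for i, (s, e) in enumerate(model.exons, start=1):
        lines.append(row("exon", s, e, f"ID={model.name}:exon{i}"))
    for iv in model.introns:
        attrs = (
            f"ID={model.name}:intron{iv.ordinal};"
            f"intron_category={iv.category};"
            f"intermediate={'true' if iv.intermediate else 'false'}"
        )
        lines.append(row("intron", iv.start, iv.end, attrs))
    with open(gff3_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _load_annotation_gff3(path: str) -> tuple[list, list, Optional[tuple], Optional[str]]:
    splice_leader = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(_SL_PRAGMA):
                splice_leader = line[len(_SL_PRAGMA):].strip()
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exons, introns, outron = [], [], None
    for feat in db.all_features(order_by=("start",)):
        s, e = feat.start - 1, feat.end  # GFF3 1-based closed -> half-open
        if feat.featuretype == "exon":
            exons.append((s, e))
        elif feat.featuretype == "intron":
            category = feat.attributes.get("intron_category", [CONVENTIONAL])[0]
            inter = feat.attributes.get("intermediate", ["false"])[0] == "true"
            introns.append((s, e, category, inter))
        elif feat.featuretype == "outron":
            outron = (s, e)
    return exons, introns, outron, splice_leader


def _load_annotation_tsv(path: str) -> tuple[list, list, Optional[tuple], Optional[str]]:
    """5-column TSV: feature, start, end, category, intermediate (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"feature": str})
    splice_leader = None
    with open(path) as fh:
        for line in fh:
            if line.startswith(_SL_PRAGMA):
                splice_leader = line[len(_SL_PRAGMA):].strip()
    exons, introns, outron = [], [], None
    for r in df.itertuples(index=False):
        s, e = int(r.start), int(r.end)
        if r.feature == "exon":
            exons.append((s, e))
        elif r.feature == "intron":
            inter = str(r.intermediate).lower() in ("true", "1")
            introns.append((s, e, str(r.category), inter))
        elif r.feature == "outron":
            outron = (s, e)
        else:
            raise GeneModelError(f"unknown feature type {r.feature!r} in {path}")
    return exons, introns, outron, splice_leader


def load_gene_model(fasta_path: str, annotation_path: str) -> GeneModel:
    """Load and validate a gene model from FASTA + GFF3/TSV annotation."""
    records = list(SeqIO.parse(fasta_path, "fasta"))
    if len(records) != 1:
        raise GeneModelError(f"{fasta_path} must contain exactly one record")
    rec = records[0]
    ext = os.path.splitext(annotation_path)[1].lower()
    if ext in (".gff3", ".gff"):
        exons, raw_introns, outron, sl = _load_annotation_gff3(annotation_path)
    else:
        exons, raw_introns, outron, sl = _load_annotation_tsv(annotation_path)
    raw_introns.sort(key=lambda t: t[0])
    introns = [
        IntronAnnotation(i, s, e, category, inter)
        for i, (s, e, category, inter) in enumerate(raw_introns, start=1)
    ]
    return GeneModel(
        name=rec.id,
        sequence=str(rec.seq),
        exons=sorted(exons),
        introns=introns,
        outron=outron,
        splice_leader=sl,
    )


def write_primers(primers: Sequence[Primer], path: str) -> None:
    rows = [
        {
            "name": p.name,
            "sequence": p.sequence,
            "orientation": p.orientation,
            "anchor_kind": p.anchor[0],
            "anchor_ordinal": p.anchor[1],
            "anchor_offset": p.anchor[2],
        }
        for p in primers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_primers(path: str, model: Optional[GeneModel] = None) -> dict[str, Primer]:
    df = pd.read_csv(path, sep="\t")
    primers = {}
    for r in df.itertuples(index=False):
        p = Primer(
            name=str(r.name),
            sequence=str(r.sequence),
            orientation=str(r.orientation),
            anchor=(str(r.anchor_kind), int(r.anchor_ordinal), int(r.anchor_offset)),
        )
        if model is not None:
            validate_primer(model, p)
        primers[p.name] = p
    return primers
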