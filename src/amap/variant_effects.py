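"""Coding-variant classification, in-silico PCR-RFLP and recessive-model
concordance.

Covers the downstream mutation analyses of a mapped candidate gene: CDS
translation under the standard genetic code, classification of a single-base
substitution given exon-relative coordinates (synonymous / missense /
nonsense, e.g. the arginine-145-to-stop change written "R145X"), simulation
of a restriction digest (NlaIII recognizes CATG and cuts 3' of the G, so a
C-to-T change can create a diagnostic site), and scoring of genotype
concordance with a fully penetrant autosomal-recessive model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}

NLAIII_MOTIF = "CATG"
NLAIII_CUT_OFFSET = 4  # cuts after the G, 3' side

CONCORDANCE_GROUPS = ("affected", "carrier", "normal_related", "control")
CONCORDANCE_GENOTYPES = ("CC", "CT", "TT")


# ---------------------------------------------------------------------------
# translation


class Translation(NamedTuple):
    protein: str
    terminated_early: bool
    stop_codon_number: int | None


def _validate_dna(seq: str, *, min_len: int = 1) -> str:
    seq = str(seq).upper()
    m = re.search(r"[^ACGT]", seq)
    if m:
        raise ValueError(
            f"non-ACGT character {m.group()!r} at position {m.start() + 1}"
        )
    if len(seq) < min_len:
        raise ValueError(f"sequence length {len(seq)} < {min_len}")
    return seq


def translate_cds(cds: str) -> Translation:
    """Translate a CDS from position 1 under the standard genetic code.

    Translation stops at the first stop codon; ``terminated_early`` is True
    iff that stop occurs before the final codon (a stop at the final codon is
    normal termination).  A trailing partial codon is ignored.
    """
    cds = _validate_dna(cds, min_len=3)
    n_codons = len(cds) // 3
    aa = str(Seq(cds[: n_codons * 3]).translate())
    stop = aa.find("*")
    if stop == -1:
        return Translation(aa, False, None)
    return Translation(aa[:stop], stop + 1 < n_codons, stop + 1)


# ---------------------------------------------------------------------------
# gene model and variant classification


@dataclass(frozen=True)
class GeneModel:
    """Exon structure and CDS over a reference sequence.

    ``exons`` are ordered, non-overlapping 1-based inclusive intervals on
    ``sequence``; ``cds_start_offset``/``cds_end_offset`` are 1-based
    positions in the spliced transcript delimiting the coding region.
    """

    exons: tuple[tuple[int, int], ...]
    cds_start_offset: int
    cds_end_offset: int
    sequence: str

    def __post_init__(self):
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError("exons must be ordered and non-overlapping")
            if end < start or end > len(self.sequence):
                raise ValueError(f"exon ({start}, {end}) outside sequence")
            prev_end = end
        t = self.transcript_length
        if not (1 <= self.cds_start_offset <= self.cds_end_offset <= t):
            raise ValueError("CDS offsets outside the spliced transcript")

    @property
    def transcript_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)

    def transcript(self) -> str:
        return "".join(self.sequence[s - 1 : e] for s, e in self.exons)

    def cds(self) -> str:
        return self.transcript()[self.cds_start_offset - 1 : self.cds_end_offset]

    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)


@dataclass(frozen=True)
class VariantEffect:
    """A classified coding substitution with codon coordinates.

    ``label`` is an HGVS-like protein shorthand: one-letter reference amino
    acid + codon number + alternate ("X" for a gained stop, "=" for a
    synonymous change), e.g. "R145X".
    """

    cds_position: int
    exon_number: int
    offset_in_exon: int
    ref_base: str
    alt_base: str
    codon_number: int
    ref_aa: str
    alt_aa: str
    effect_class: str
    label: str


def classify_variant(
    model: GeneModel,
    exon_number: int,
    offset_in_exon: int,
    ref: str,
    alt: str,
) -> VariantEffect:
    """Map an exon-relative substitution to its codon and classify it.

    ``exon_number`` and ``offset_in_exon`` are 1-based; the offset must fall
    in the coding portion of that exon and ``ref`` must match the model
    sequence there.
    """
    ref, alt = str(ref).upper(), str(alt).upper()
    if ref == alt:
        raise ValueError("ref and alt base are identical")
    for base, role in ((ref, "ref"), (alt, "alt")):
        if base not in "ACGT":
            raise ValueError(f"{role} base {base!r} is not a DNA letter")
    if not 1 <= exon_number <= len(model.exons):
        raise ValueError(f"exon {exon_number} outside model (1..{len(model.exons)})")
    lengths = model.exon_lengths()
    if not 1 <= offset_in_exon <= lengths[exon_number - 1]:
        raise ValueError(
            f"offset {offset_in_exon} outside exon {exon_number} "
            f"(length {lengths[exon_number - 1]})"
        )
    transcript_pos = sum(lengths[: exon_number - 1]) + offset_in_exon
    cds_position = transcript_pos - (model.cds_start_offset - 1)
    cds = model.cds()
    if not 1 <= cds_position <= len(cds):
        raise ValueError(
            f"exon {exon_number} offset {offset_in_exon} falls outside the CDS"
        )
    expected = cds[cds_position - 1]
    if expected != ref:
        raise ValueError(
            f"ref base mismatch at CDS position {cds_position}: "
            f"expected {expected!r}, got {ref!r}"
        )
    codon_number = (cds_position + 2) // 3
    codon_start = (codon_number - 1) * 3
    ref_codon = cds[codon_start : codon_start + 3]
    within = cds_position - 1 - codon_start
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1 :]
    ref_aa = _aa(ref_codon)
    alt_aa = _aa(alt_codon)
    if alt_aa == "X" and ref_aa != "X":
        effect, suffix = "nonsense", "X"
    elif alt_aa == ref_aa:
        effect, suffix = "synonymous", "="
    else:
        effect, suffix = "missense", alt_aa
    return VariantEffect(
        cds_position=cds_position,
        exon_number=exon_number,
        offset_in_exon=offset_in_exon,
        ref_base=ref,
        alt_base=alt,
        codon_number=codon_number,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        effect_class=effect,
        label=f"{ref_aa}{codon_number}{suffix}",
    )


def _aa(codon: str) -> str:
    """One-letter amino acid, with stop written X (as in R145X)."""
    aa = str(Seq(codon).translate())
    return "X" if aa == "*" else aa


# ---------------------------------------------------------------------------
# restriction digest


def digest(
    seq: str,
    motif: str = NLAIII_MOTIF,
    cut_offset: int = NLAIII_CUT_OFFSET,
) -> list[int]:
    """Ordered fragment lengths from cutting at every motif occurrence.

    All (possibly overlapping) occurrences on the given strand are found;
    each is cut after ``cut_offset`` bases.  Fragment lengths always sum to
    the sequence length and number one more than the cut sites.  Single-
    strand scanning suffices for a palindromic-site enzyme like NlaIII at
    the band-counting level of abstraction.
    """
    seq = _validate_dna(seq)
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0 <= cut_offset <= len(motif):
        raise ValueError(f"cut_offset {cut_offset} outside 0..{len(motif)}")
    motif = _validate_dna(motif)
    cuts = []
    i = seq.find(motif)
    while i != -1:
        cuts.append(i + cut_offset)
        i = seq.find(motif, i + 1)
    cuts = sorted(set(cuts))
    bounds = [0] + cuts + [len(seq)]
    return [bounds[k + 1] - bounds[k] for k in range(len(bounds) - 1)]


@dataclass(frozen=True)
class DigestPattern:
    """Per-allele fragment lengths and the pooled set of distinct bands.

    A band is a distinct fragment length (equal lengths co-migrate on a
    gel), so a heterozygote's bands are the union over its two alleles.
    """

    allele_fragments: tuple[tuple[int, ...], ...]
    band_lengths: frozenset[int]

    @property
    def n_bands(self) -> int:
        return len(self.band_lengths)


def band_pattern(
    amplicon_ref: str,
    variant: tuple[int, str, str],
    genotype: str,
    *,
    motif: str = NLAIII_MOTIF,
    cut_offset: int = NLAIII_CUT_OFFSET,
) -> DigestPattern:
    """Predict the gel band pattern of a genotype's PCR-RFLP digest.

    ``variant`` is (1-based position in the amplicon, ref base, alt base);
    ``genotype`` is a two-letter string over {ref, alt} bases, e.g. "CC",
    "CT" or "TT" for a C-to-T substitution.
    """
    amplicon_ref = _validate_dna(amplicon_ref)
    position, ref, alt = variant
    ref, alt = str(ref).upper(), str(alt).upper()
    if not 1 <= position <= len(amplicon_ref):
        raise ValueError(f"variant position {position} outside amplicon")
    if amplicon_ref[position - 1] != ref:
        raise ValueError(
            f"amplicon has {amplicon_ref[position - 1]!r} at position {position}, "
            f"expected ref {ref!r}"
        )
    alt_seq = amplicon_ref[: position - 1] + alt + amplicon_ref[position:]
    by_base = {ref: amplicon_ref, alt: alt_seq}
    genotype = str(genotype).upper()
    if len(genotype) != 2 or any(b not in by_base for b in genotype):
        raise ValueError(
            f"genotype {genotype!r} must be two letters over {sorted(by_base)}"
        )
    fragments = tuple(tuple(digest(by_base[b], motif, cut_offset)) for b in genotype)
    bands = frozenset(length for allele in fragments for length in allele)
    return DigestPattern(allele_fragments=fragments, band_lengths=bands)


# ---------------------------------------------------------------------------
# recessive-model concordance


@dataclass(frozen=True)
class ConcordanceRow:
    group: str
    genotype: str
    count: int

    def __post_init__(self):
        if self.group not in CONCORDANCE_GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.genotype.upper() not in {"CC", "CT", "TC", "TT"}:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.count < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ConcordanceTable:
    rows: tuple[ConcordanceRow, ...]

    @classmethod
    def from_counts(cls, counts: Sequence[tuple[str, str, int]]) -> "ConcordanceTable":
        return cls(tuple(ConcordanceRow(g, gt, int(c)) for g, gt, c in counts))

    def total(self) -> int:
        return sum(r.count for r in self.rows)


@dataclass(frozen=True)
class ConcordanceResult:
    per_group: dict[str, float | None]
    overall: float


def _normalized_genotype(genotype: str) -> str:
    return {"TC": "CT"}.get(genotype.upper(), genotype.upper())


def _is_concordant(group: str, genotype: str) -> bool:
    genotype = _normalized_genotype(genotype)
    if group == "affected":
        return genotype == "TT"
    if group == "carrier":
        return genotype == "CT"
    return genotype != "TT"  # normal_related / control: not homozygous risk


def concordance(table: ConcordanceTable) -> ConcordanceResult:
    """Score a genotype table against the fully penetrant recessive model
    with risk allele T: affected must be TT, obligate carriers CT, and
    phenotypically normal individuals anything but TT.

    Per-group rates are reported separately (None for an absent group); the
    pooled rate uses every individual in the table.
    """
    if table.total() == 0:
        raise ValueError("concordance undefined on an empty table")
    per_group: dict[str, float | None] = {}
    pooled_hits = 0
    for group in CONCORDANCE_GROUPS:
        rows = [r for r in table.rows if r.group == group]
        n = sum(r.count for r in rows)
        if n == 0:
            per_group[group] = None
            continue
        hits = sum(r.count for r in rows if _is_concordant(group, r.genotype))
        per_group[group] = hits / n
        pooled_hits += hits
    return ConcordanceResult(per_group=per_group, overall=pooled_hits / table.total())
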