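"""Synthetic study cohort: pedigree, chip genotypes, gene and amplicon fixtures.

Emulates the input universe of a recessive-disease mapping study in sheep:
an outcross/backcross pedigree segregating a recessive causal allele (a
carrier ram mated to unrelated ewes, F1 daughters mated back to the ram), a
~54K-SNP array genotyped on 17 affected and 3 carrier animals, three
autozygous segments planted around the causal site (125, 19 and 11 SNPs by
default), per-cell no-calls with per-SNP QC metadata, a six-exon candidate
gene fixture carrying an arginine-to-stop substitution at codon 145, and the
genotype table for recessive-model concordance scoring.

Genotypes arise by gene-dropping founder haplotypes through the pedigree
with Poisson recombination.  On causal-lineage meioses the gamete is
constrained to copy the causal-haplotype-bearing parental chromosome exactly
over each planted segment (the implied crossovers fall in the flanking
inter-SNP gaps), so every genotype stays Mendelian-consistent while the
planted segment boundaries are exact at the haplotype level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
import pandas as pd

from .genotype_io import (
    GenotypeMatrix,
    NOCALL,
    SnpMap,
    write_genotypes_long,
    write_map,
    write_qc,
    write_sample_sheet,
)
from .variant_effects import ConcordanceTable, GeneModel

# Approximate autosome + X lengths (Mb) used to lay out the synthetic map;
# chromosome "6" and "15" must accommodate the default planted segments.
CHROM_LENGTHS_MB = (
    275, 248, 224, 119, 107, 126, 100, 90, 94, 86, 62, 79, 83, 62, 80,
    71, 72, 68, 60, 51, 50, 50, 62, 42, 45, 44, 135,
)

# Default planted layout mirroring the study: (chromosome, anchor bp, n SNPs).
STUDY_SEGMENTS = (("6", 109_334_543, 125), ("6", 118_884_834, 19), ("15", 1_131_166, 11))
CAUSAL_ANCHOR = ("6", 112_213_795)


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the study's design: 54,241 mapped SNPs, 17 affected
    + 3 carrier chip samples, 24 phenotypically normal relatives and 46
    unrelated controls for the concordance table, three planted autozygous
    segments of 125/19/11 SNPs with the causal SNP inside the largest, MAF
    uniform on (0.05, 0.5), 1% no-calls and ~1 cM/Mb recombination.

    ``planted_segments`` entries are (chromosome, chromosome-local start
    index, n_snps); None resolves the study layout against the generated
    map by base-pair anchor.  ``causal`` is (chromosome, offset within
    segment 1); None anchors it near the middle of segment 1.
    """

    n_snps: int = 54_241
    n_chromosomes: int = 27
    n_affected: int = 17
    n_carrier: int = 3
    n_normal_related: int = 24
    n_controls: int = 46
    planted_segments: tuple[tuple[str, int, int], ...] | None = None
    causal: tuple[str, int] | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    nocall_rate: float = 0.01
    recomb_rate_per_mb: float = 0.01
    qc_fail_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_chromosomes <= len(CHROM_LENGTHS_MB):
            raise ValueError(
                f"n_chromosomes must be in 1..{len(CHROM_LENGTHS_MB)}"
            )
        for name, value in (
            ("n_snps", self.n_snps), ("n_affected", self.n_affected),
            ("n_carrier", self.n_carrier),
            ("n_normal_related", self.n_normal_related),
            ("n_controls", self.n_controls),
        ):
            if value < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    sire: str | None
    dam: str | None
    generation: str  # founder / F1 / F2
    status: str      # affected / carrier / normal


@dataclass
class Pedigree:
    individuals: list[PedigreeMember]

    def __post_init__(self):
        seen: set[str] = set()
        for member in self.individuals:
            for parent in (member.sire, member.dam):
                if parent is not None and parent not in seen:
                    raise ValueError(
                        f"{member.id}: parent {parent} not defined before offspring"
                    )
            seen.add(member.id)

    def member(self, id: str) -> PedigreeMember:
        for m in self.individuals:
            if m.id == id:
                return m
        raise KeyError(id)

    def __len__(self) -> int:
        return len(self.individuals)


@dataclass(frozen=True)
class PlantedSegment:
    """Realized planted segment in global contiguous-index coordinates."""

    chromosome: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int

    @property
    def n_snps(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class SimTruth:
    """Ground truth for one simulated cohort."""

    segments: list[PlantedSegment]
    causal_index: int
    causal_chromosome: str
    causal_bp: int
    affected_ids: list[str]
    carrier_ids: list[str]
    normal_related_causal: list[str]          # "CT"/"CC" per relative
    f2_causal_draws: list[str]                # raw backcross draws, pre-selection
    haplotypes: dict[str, np.ndarray]         # id -> (2, n_snps) int8
    qc_forced_fail: np.ndarray | None = None  # SNP indices given failing QC


# ---------------------------------------------------------------------------
# map construction


def _build_map(cfg: SimConfig, rng: np.random.Generator) -> SnpMap:
    lengths = np.array(CHROM_LENGTHS_MB[: cfg.n_chromosomes], dtype=float)
    share = lengths / lengths.sum()
    counts = np.floor(share * cfg.n_snps).astype(int)
    # largest-remainder top-up to hit n_snps exactly
    remainder = share * cfg.n_snps - counts
    for i in np.argsort(-remainder)[: cfg.n_snps - counts.sum()]:
        counts[i] += 1
    names: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    for c, (n_c, length_mb) in enumerate(zip(counts, lengths), start=1):
        if n_c == 0:
            continue
        spacing = length_mb * 1e6 / n_c
        gaps = rng.uniform(0.4, 1.6, n_c) * spacing
        pos = np.cumsum(gaps).astype(np.int64)
        pos = np.maximum.accumulate(pos) + np.arange(n_c)  # strictly increasing
        chrom = str(c)
        chroms.extend([chrom] * n_c)
        positions.extend(pos.tolist())
        names.extend(f"OAR{chrom}_{p}.1" for p in pos)
    frame = pd.DataFrame(
        {"snp_name": names, "chromosome": chroms, "position_bp": positions}
    )
    return SnpMap(frame)


def _chrom_blocks(snp_map: SnpMap, cfg: SimConfig):
    lengths = {str(i + 1): CHROM_LENGTHS_MB[i] * 1e6 for i in range(cfg.n_chromosomes)}
    return [
        (chrom, lo, hi, snp_map.positions[lo:hi].astype(float), lengths[chrom])
        for chrom, lo, hi in snp_map.chrom_slices()
    ]


def _resolve_segments(cfg: SimConfig, snp_map: SnpMap) -> list[PlantedSegment]:
    slices = {chrom: (lo, hi) for chrom, lo, hi in snp_map.chrom_slices()}
    positions = snp_map.positions
    resolved: list[PlantedSegment] = []
    if cfg.planted_segments is None:
        layout = []
        for chrom, anchor_bp, n in STUDY_SEGMENTS:
            if chrom not in slices:
                raise ValueError(f"default layout needs chromosome {chrom!r}")
            lo, hi = slices[chrom]
            local = int(np.argmin(np.abs(positions[lo:hi] - anchor_bp)))
            layout.append((chrom, local, n))
    else:
        layout = [(str(c), int(s), int(n)) for c, s, n in cfg.planted_segments]
    for chrom, local_start, n in layout:
        if chrom not in slices:
            raise ValueError(f"planted segment on unknown chromosome {chrom!r}")
        lo, hi = slices[chrom]
        start = lo + local_start
        end = start + n - 1
        if local_start < 0 or end >= hi:
            raise ValueError(
                f"planted segment ({chrom}, {local_start}, {n}) exceeds chromosome"
            )
        resolved.append(
            PlantedSegment(
                chromosome=chrom,
                start_index=start,
                end_index=end,
                start_bp=int(positions[start]),
                end_bp=int(positions[end]),
            )
        )
    resolved.sort(key=lambda s: s.start_index)
    for a, b in zip(resolved, resolved[1:]):
        if a.chromosome == b.chromosome and b.start_index <= a.end_index:
            raise ValueError("planted segments overlap")
    return resolved


def _resolve_causal(
    cfg: SimConfig, segments: list[PlantedSegment], snp_map: SnpMap
) -> int:
    if not segments:
        raise ValueError("need at least one planted segment for the causal SNP")
    seg1 = segments[0] if cfg.planted_segments is not None else None
    if cfg.planted_segments is None:
        # study layout: segment order follows STUDY_SEGMENTS; anchor by bp
        chrom, anchor_bp = CAUSAL_ANCHOR
        candidates = [s for s in segments if s.chromosome == chrom]
        seg1 = max(candidates, key=lambda s: s.n_snps)
        local = int(
            np.argmin(
                np.abs(
                    snp_map.positions[seg1.start_index : seg1.end_index + 1]
                    - anchor_bp
                )
            )
        )
        return seg1.start_index + local
    seg1 = max(segments, key=lambda s: s.n_snps)
    if cfg.causal is None:
        return seg1.start_index + seg1.n_snps // 2
    chrom, offset = cfg.causal
    matches = [s for s in segments if s.chromosome == str(chrom)]
    if not matches:
        raise ValueError(f"causal chromosome {chrom!r} has no planted segment")
    seg = max(matches, key=lambda s: s.n_snps)
    if not 0 <= int(offset) < seg.n_snps:
        raise ValueError("causal offset outside segment 1")
    return seg.start_index + int(offset)


# ---------------------------------------------------------------------------
# gene drop


def _meiosis(
    rng: np.random.Generator,
    haps: np.ndarray,
    blocks,
    rate_per_mb: float,
    constraints: dict[str, list[tuple[int, int]]] | None = None,
) -> np.ndarray:
    """One gamete: per-chromosome Poisson crossovers between the parent's
    two haplotypes.  ``constraints`` maps chromosome -> [(local_lo,
    local_hi)] index windows over which the gamete must copy haplotype 0
    (the causal-bearing chromosome); implied breakpoints land in the
    flanking inter-SNP gaps."""
    gamete = np.empty(haps.shape[1], dtype=np.int8)
    for chrom, lo, hi, pos, length_bp in blocks:
        lam = (length_bp / 1e6) * rate_per_mb
        n_xo = rng.poisson(lam)
        xo = np.sort(rng.uniform(0, length_bp, n_xo))
        start = rng.integers(0, 2)
        hap_idx = (start + np.searchsorted(xo, pos)) % 2
        if constraints:
            for c_lo, c_hi in constraints.get(chrom, ()):
                hap_idx[c_lo : c_hi + 1] = 0
        block = np.where(hap_idx == 0, haps[0, lo:hi], haps[1, lo:hi])
        gamete[lo:hi] = block
    return gamete


def simulate_cohort(cfg: SimConfig) -> tuple[GenotypeMatrix, Pedigree, SimTruth]:
    """Generate the chip cohort, its pedigree and the planted-segment truth.

    The chip matrix contains the affected F2 animals plus the carrier group
    (the ram and carrier F1 daughters), as in the study; the phenotypically
    normal relatives and the unrelated controls exist only as causal-locus
    genotypes in the truth record (they were not array-genotyped).
    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    snp_map = _build_map(cfg, rng)
    segments = _resolve_segments(cfg, snp_map)
    causal_index = _resolve_causal(cfg, segments, snp_map)
    causal_chrom = snp_map.chromosomes[causal_index]
    blocks = _chrom_blocks(snp_map, cfg)
    n = len(snp_map)

    # population allele frequencies (freq of the B allele), minor allele
    # assigned to A or B at random; the causal risk allele is private to the
    # carrier ram's haplotype
    maf = rng.uniform(*cfg.maf_range, n)
    q = np.where(rng.random(n) < 0.5, maf, 1.0 - maf)

    def founder_haps() -> np.ndarray:
        return (rng.random((2, n)) < q).astype(np.int8)

    haplotypes: dict[str, np.ndarray] = {}
    members: list[PedigreeMember] = []

    ram = "RAM"
    ram_haps = founder_haps()
    ram_haps[:, causal_index] = (1, 0)  # hap 0 carries the risk allele
    haplotypes[ram] = ram_haps
    members.append(PedigreeMember(ram, None, None, "founder", "carrier"))

    def add_ewe(tag: str) -> str:
        ewe_id = f"EWE_{tag}"
        haps = founder_haps()
        haps[:, causal_index] = 0  # ewes are unrelated non-carriers
        haplotypes[ewe_id] = haps
        members.append(PedigreeMember(ewe_id, None, None, "founder", "normal"))
        return ewe_id

    # segment windows, chromosome-local, for constrained meioses
    local = {}
    for chrom, lo, hi, _pos, _L in blocks:
        local[chrom] = lo
    all_windows: dict[str, list[tuple[int, int]]] = {}
    for seg in segments:
        all_windows.setdefault(seg.chromosome, []).append(
            (seg.start_index - local[seg.chromosome], seg.end_index - local[seg.chromosome])
        )
    seg1 = max(segments, key=lambda s: s.n_snps) if segments else None
    seg1_window = (
        {seg1.chromosome: [(seg1.start_index - local[seg1.chromosome],
                            seg1.end_index - local[seg1.chromosome])]}
        if seg1 is not None
        else {}
    )

    def conceive(
        child_id: str,
        sire_id: str,
        dam_id: str,
        generation: str,
        status: str,
        sire_constraints=None,
        dam_constraints=None,
    ) -> str:
        paternal = _meiosis(
            rng, haplotypes[sire_id], blocks, cfg.recomb_rate_per_mb, sire_constraints
        )
        maternal = _meiosis(
            rng, haplotypes[dam_id], blocks, cfg.recomb_rate_per_mb, dam_constraints
        )
        haplotypes[child_id] = np.stack([paternal, maternal])
        members.append(PedigreeMember(child_id, sire_id, dam_id, generation, status))
        return child_id

    # affected F2: backcross of a constrained carrier F1 daughter to the ram,
    # both transmissions forced to deliver the causal haplotype across every
    # planted segment
    affected_ids: list[str] = []
    for k in range(cfg.n_affected):
        ewe = add_ewe(f"A{k + 1:02d}")
        dam = conceive(
            f"DAM_{k + 1:02d}", ram, ewe, "F1", "carrier",
            sire_constraints=all_windows,
        )
        affected_ids.append(
            conceive(
                f"AFF_{k + 1:02d}", ram, dam, "F2", "affected",
                sire_constraints=all_windows, dam_constraints=all_windows,
            )
        )

    # genotyped carrier group: the ram plus carrier F1 daughters whose
    # paternal gamete is forced over segment 1 only (their state in the
    # other segments is left to inheritance)
    carrier_ids = [ram] if cfg.n_carrier > 0 else []
    for k in range(max(cfg.n_carrier - 1, 0)):
        ewe = add_ewe(f"C{k + 1:02d}")
        carrier_ids.append(
            conceive(
                f"CAR_{k + 1:02d}", ram, ewe, "F1", "carrier",
                sire_constraints=seg1_window,
            )
        )

    # phenotypically normal relatives: unconstrained F1 outcross lambs and
    # F2 backcross lambs; backcross draws that come out homozygous-risk
    # would be affected, so they are recorded but not kept as "normal"
    def causal_genotype(individual: str) -> str:
        dose = int(haplotypes[individual][:, causal_index].sum())
        return ("CC", "CT", "TT")[dose]

    normal_related_causal: list[str] = []
    f2_causal_draws: list[str] = []
    k_f1 = k_f2 = 0
    guard = 0
    while len(normal_related_causal) < cfg.n_normal_related:
        guard += 1
        if guard > 50 * max(cfg.n_normal_related, 1):
            raise RuntimeError("normal-related sampling failed to converge")
        if len(normal_related_causal) % 2 == 0 or cfg.n_affected == 0:
            k_f1 += 1
            ewe = add_ewe(f"N{k_f1:02d}")
            lamb = conceive(f"NRF1_{k_f1:02d}", ram, ewe, "F1", "normal")
            normal_related_causal.append(causal_genotype(lamb))
        else:
            k_f2 += 1
            dam = f"DAM_{(k_f2 - 1) % cfg.n_affected + 1:02d}"
            lamb = conceive(f"NRF2_{k_f2:02d}", ram, dam, "F2", "normal")
            draw = causal_genotype(lamb)
            f2_causal_draws.append(draw)
            if draw == "TT":
                # homozygous risk = affected phenotype; not a "normal" relative
                members[-1] = PedigreeMember(lamb, ram, dam, "F2", "affected")
            else:
                normal_related_causal.append(draw)

    pedigree = Pedigree(members)

    # chip matrix: affected + carriers, with per-cell no-calls
    chip_ids = affected_ids + carrier_ids
    statuses = ["affected"] * len(affected_ids) + ["carrier"] * len(carrier_ids)
    calls = np.zeros((len(chip_ids), n), dtype=np.int8)
    for row, individual in enumerate(chip_ids):
        calls[row] = haplotypes[individual].sum(axis=0)
    nocall_mask = rng.random(calls.shape) < cfg.nocall_rate
    calls[nocall_mask] = NOCALL

    matrix = GenotypeMatrix(chip_ids, statuses, calls, snp_map)

    # per-SNP QC metadata: call rate observed on the chip samples, GenTrain
    # drawn high with a configurable fraction of forced failures kept off
    # the planted segments (and their 2-SNP flanks) so the planted truth is
    # invariant under QC filtering
    gentrain = rng.uniform(0.35, 0.99, n)
    protected = np.zeros(n, dtype=bool)
    for seg in segments:
        protected[max(seg.start_index - 2, 0) : seg.end_index + 3] = True
    eligible = np.flatnonzero(~protected)
    n_fail = min(int(round(cfg.qc_fail_rate * n)), eligible.size)
    forced_fail = rng.choice(eligible, size=n_fail, replace=False) if n_fail else np.array([], dtype=int)
    gentrain[forced_fail] = rng.uniform(0.02, 0.24, n_fail)
    qc = pd.DataFrame(
        {
            "snp_name": snp_map.names,
            "call_rate": matrix.call_rates(),
            "gentrain": gentrain,
        }
    )
    matrix = matrix.attach_qc(qc)

    truth = SimTruth(
        segments=segments,
        causal_index=causal_index,
        causal_chromosome=str(causal_chrom),
        causal_bp=int(snp_map.positions[causal_index]),
        affected_ids=affected_ids,
        carrier_ids=carrier_ids,
        normal_related_causal=normal_related_causal,
        f2_causal_draws=f2_causal_draws,
        haplotypes=haplotypes,
        qc_forced_fail=np.sort(forced_fail),
    )
    return matrix, pedigree, truth


# ---------------------------------------------------------------------------
# concordance table


def make_concordance_table(cfg: SimConfig, truth: SimTruth) -> ConcordanceTable:
    """Tally causal-locus genotypes by group, as for a diagnostic PCR-RFLP
    survey: affected and carrier genotypes come from the simulated
    haplotypes, the normal relatives from the recorded backcross/outcross
    draws, and the unrelated controls are homozygous reference (the risk
    allele is private to the study flock)."""
    counts: dict[tuple[str, str], int] = {}

    def bump(group: str, genotype: str, by: int = 1):
        counts[(group, genotype)] = counts.get((group, genotype), 0) + by

    for individual in truth.affected_ids:
        dose = int(truth.haplotypes[individual][:, truth.causal_index].sum())
        bump("affected", ("CC", "CT", "TT")[dose])
    for individual in truth.carrier_ids:
        dose = int(truth.haplotypes[individual][:, truth.causal_index].sum())
        bump("carrier", ("CC", "CT", "TT")[dose])
    for genotype in truth.normal_related_causal:
        bump("normal_related", genotype)
    if cfg.n_controls:
        bump("control", "CC", cfg.n_controls)
    rows = [(g, gt, c) for (g, gt), c in sorted(counts.items())]
    return ConcordanceTable.from_counts(rows)


# ---------------------------------------------------------------------------
# gene / amplicon fixture


@dataclass(frozen=True)
class GeneFixture:
    """Six-exon gene model with the codon-145 arginine-to-stop substitution
    and the PCR-RFLP amplicon around it.

    The gene spans >16 kb with exons 1-5 contributing 183 coding nt and
    exon 6 the remaining 1341 nt (~88% of the 1524-nt ORF), so the exon-6
    offset-250 C>T lands in codon 145 (CGA -> TGA).  The amplicon carries
    one constitutive CATG site; the T allele creates a second strictly
    inside one constitutive-digest fragment, and all fragment lengths are
    pairwise distinct, so genotypes CC/TT/CT give 2/3/4 gel bands.  The
    amplicon lies entirely within exon 6, hence the transcript-level
    (RT-PCR) amplicon is the identical sequence.
    """

    model: GeneModel
    cds: str
    amplicon: str
    amplicon_variant_pos: int  # 1-based position of the C in the amplicon
    exon_number: int
    offset_in_exon: int
    ref_base: str
    alt_base: str

    @property
    def variant(self) -> tuple[int, str, str]:
        return (self.amplicon_variant_pos, self.ref_base, self.alt_base)


_EXON_CODING = (45, 30, 30, 39, 39, 1341)  # nt per exon; total 1524 = 508 codons
_N_CODONS = 1524 // 3
_STOPS = ("TAA", "TAG", "TGA")
# cds coordinates (1-based) that carry fixture-critical content
_FORCED_CODONS = {1: "ATG", 122: "CAT", 144: "GCA", 145: "CGA", _N_CODONS: "TGA"}
_AMPLICON_CDS_START = 314  # 1-based, inside exon 6 (CDS positions 314..563)
_AMPLICON_LENGTH = 250


def make_gene_fixture(cfg: SimConfig | None = None) -> GeneFixture:
    """Build the deterministic gene-model + amplicon fixture (seeded from
    ``cfg.seed``; background codons vary with the seed, the engineered
    sites do not)."""
    seed = cfg.seed if cfg is not None else 0
    rng = np.random.default_rng(np.uint32(seed) ^ np.uint32(0x6E1A))
    bases = "ACGT"
    non_stop = [a + b + c for a in bases for b in bases for c in bases
                if a + b + c not in _STOPS]

    codons = [non_stop[i] for i in rng.integers(0, len(non_stop), _N_CODONS)]
    for number, codon in _FORCED_CODONS.items():
        codons[number - 1] = codon
    # codon 123 must start with G to complete the constitutive CATG after
    # codon 122 ("CAT"); G-initial codons are never stops
    codons[122] = "G" + codons[122][1:]

    protected = set()
    for number in (1, 122, 123, 144, 145, _N_CODONS):
        protected.update(range((number - 1) * 3 + 1, number * 3 + 1))

    intended_ref = {(122 - 1) * 3 + 1}            # CATG at CDS 364..367
    variant_cds = (145 - 1) * 3 + 1               # the C of codon 145, CDS 433
    intended_alt = intended_ref | {variant_cds - 2}  # C>T creates CATG at 431..434

    def occurrences(s: str) -> set[int]:
        found, i = set(), s.find("CATG")
        while i != -1:
            found.add(i + 1)
            i = s.find("CATG", i + 1)
        return found

    cds = "".join(codons)
    for _ in range(10_000):
        alt_cds = cds[: variant_cds - 1] + "T" + cds[variant_cds:]
        stray = (occurrences(cds) - intended_ref) | (occurrences(alt_cds) - intended_alt)
        if not stray:
            break
        start = min(stray)
        # break the stray site by rewriting one unprotected base inside it
        editable = [p for p in range(start, start + 4) if p not in protected]
        pos = editable[rng.integers(0, len(editable))]
        codon_number = (pos + 2) // 3
        old_codon = cds[(codon_number - 1) * 3 : codon_number * 3]
        within = (pos - 1) % 3
        for base in rng.permutation(list(bases)):
            candidate = old_codon[:within] + base + old_codon[within + 1 :]
            if base != old_codon[within] and candidate not in _STOPS:
                cds = (
                    cds[: (codon_number - 1) * 3] + candidate + cds[codon_number * 3 :]
                )
                break
    else:  # pragma: no cover - construction always converges quickly
        raise RuntimeError("could not sanitize fixture CDS")

    # genomic assembly: six fully coding exons separated by ~2.9-kb introns
    intron_len = 2_938
    intron_bases = np.array(list(bases))
    exons: list[tuple[int, int]] = []
    pieces: list[str] = []
    cursor = 0
    offset = 0
    for k, length in enumerate(_EXON_CODING):
        exon_seq = cds[offset : offset + length]
        exons.append((cursor + 1, cursor + length))
        pieces.append(exon_seq)
        cursor += length
        offset += length
        if k < len(_EXON_CODING) - 1:
            intron = "".join(intron_bases[rng.integers(0, 4, intron_len)])
            intron = intron.replace("CATG", "CTTG")  # keep digest sites exon-borne
            pieces.append(intron)
            cursor += intron_len
    sequence = "".join(pieces)
    model = GeneModel(
        exons=tuple(exons),
        cds_start_offset=1,
        cds_end_offset=len(cds),
        sequence=sequence,
    )

    amplicon = cds[_AMPLICON_CDS_START - 1 : _AMPLICON_CDS_START - 1 + _AMPLICON_LENGTH]
    return GeneFixture(
        model=model,
        cds=cds,
        amplicon=amplicon,
        amplicon_variant_pos=variant_cds - _AMPLICON_CDS_START + 1,
        exon_number=6,
        offset_in_exon=variant_cds - sum(_EXON_CODING[:5]),
        ref_base="C",
        alt_base="T",
    )


def write_gene_fixture(fixture: GeneFixture, outdir) -> None:
    """FASTA + JSON sidecar for the gene fixture (synthetic sequences)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    SeqIO.write(
        SeqRecord(Seq(fixture.model.sequence), id="synthetic_gene",
                  description="synthetic six-exon candidate gene"),
        outdir / "gene.fa", "fasta",
    )
    SeqIO.write(
        SeqRecord(Seq(fixture.amplicon), id="synthetic_amplicon",
                  description="synthetic exon-6 PCR amplicon"),
        outdir / "amplicon.fa", "fasta",
    )
    sidecar = {
        "exons": list(map(list, fixture.model.exons)),
        "cds_start_offset": fixture.model.cds_start_offset,
        "cds_end_offset": fixture.model.cds_end_offset,
        "variant": {
            "exon_number": fixture.exon_number,
            "offset_in_exon": fixture.offset_in_exon,
            "amplicon_position": fixture.amplicon_variant_pos,
            "ref": fixture.ref_base,
            "alt": fixture.alt_base,
        },
    }
    (outdir / "gene_model.json").write_text(json.dumps(sidecar, indent=2))


# ---------------------------------------------------------------------------
# LD panel fixture


def make_ld_panel(
    n_individuals: int = 60, seed: int = 0
) -> tuple[GenotypeMatrix, list[str], str]:
    """Nine-SNP exon-6-style panel: four SNPs ride one shared haplotype
    background (complete mutual LD) while the causal SNP sits on a distinct
    haplotype, so its pairwise r^2 with the block is < 1.

    Returns (matrix, block_snp_names, causal_snp_name).
    """
    rng = np.random.default_rng(seed)
    n_snps = 9
    block = [1, 3, 5, 7]
    causal = 4
    others = [0, 2, 6, 8]
    # three haplotypes over the panel; block alleles co-vary, the risk
    # allele rides only haplotype h3
    h1 = np.zeros(n_snps, dtype=np.int8)
    h2 = np.zeros(n_snps, dtype=np.int8)
    h3 = np.zeros(n_snps, dtype=np.int8)
    h1[block] = 1
    h3[causal] = 1
    h1[others] = (1, 0, 1, 0)
    h2[others] = (0, 1, 1, 0)
    h3[others] = (0, 0, 0, 1)
    pool = np.stack([h1, h2, h3])
    freqs = np.array([0.35, 0.40, 0.25])
    draws = rng.choice(3, size=2 * n_individuals, p=freqs)
    haps = pool[draws]
    calls = (haps[0::2] + haps[1::2]).astype(np.int8)
    names = [f"ex6_snp{k + 1}" if k != causal else "ex6_R145X" for k in range(n_snps)]
    snp_map = SnpMap(
        pd.DataFrame(
            {
                "snp_name": names,
                "chromosome": ["6"] * n_snps,
                "position_bp": (np.arange(n_snps) + 1) * 137 + 112_213_000,
            }
        )
    )
    matrix = GenotypeMatrix(
        [f"S{i + 1:02d}" for i in range(n_individuals)],
        ["unknown"] * n_individuals,
        calls,
        snp_map,
    )
    return matrix, [names[k] for k in block], names[causal]


# ---------------------------------------------------------------------------
# cohort writers (same dialects genotype_io reads)


def write_cohort(outdir, matrix: GenotypeMatrix, pedigree: Pedigree, truth: SimTruth) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(matrix.snp_map, outdir / "map.tsv")
    write_genotypes_long(matrix, outdir / "report.csv")
    write_sample_sheet(matrix, outdir / "samples.csv")
    if matrix.qc is not None:
        write_qc(matrix, outdir / "qc.csv")
    pd.DataFrame(
        [
            {
                "id": m.id,
                "sire": m.sire or "",
                "dam": m.dam or "",
                "generation": m.generation,
                "status": m.status,
            }
            for m in pedigree.individuals
        ]
    ).to_csv(outdir / "pedigree.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "segments": [
                    {
                        "chromosome": s.chromosome,
                        "start_index": s.start_index,
                        "end_index": s.end_index,
                        "start_bp": s.start_bp,
                        "end_bp": s.end_bp,
                        "n_snps": s.n_snps,
                    }
                    for s in truth.segments
                ],
                "causal": {
                    "index": truth.causal_index,
                    "chromosome": truth.causal_chromosome,
                    "position_bp": truth.causal_bp,
                },
                "normal_related_causal": truth.normal_related_causal,
            },
            indent=2,
        )
    )
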