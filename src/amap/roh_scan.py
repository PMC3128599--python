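"""Consensus-homozygosity scan for autozygosity mapping of recessive loci.

The scan localizes a recessive mutation by finding chromosome stretches at
which *every* affected individual is homozygous (identity by descent from a
shared carrier ancestor), then checking that carriers are not homozygous for
the same alleles across those stretches.  It proceeds SNP by SNP:

1. count the four genotype classes (homA/het/homB/no-call) in the case group;
2. compute genotype frequencies with no-calls excluded from the denominator;
3. call a SNP *consensus homozygous* when the top frequency equals 1 and the
   top genotype is a homozygote;
4. report maximal runs of consecutive consensus-homozygous SNPs longer than
   a threshold (default: more than 10 informative SNPs);
5. re-check each run in the carrier group.

"Consecutive" is defined over the map's contiguous index (post-QC if QC was
applied).  SNPs with no data at all in the group (all no-calls) are
*uninformative*: they neither break a run nor count toward its threshold,
and run boundaries are trimmed to informative SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genotype_io import (
    GenotypeMatrix,
    HET,
    HOM_A,
    HOM_B,
    NOCALL,
    SnpMap,
    chromosome_key,
    split_by_status,
)

# consensus state labels / codes
CONSENSUS_HOM_A = "consensus_homA"
CONSENSUS_HOM_B = "consensus_homB"
NON_CONSENSUS = "non_consensus"
UNINFORMATIVE = "uninformative"

STATE_LABELS = (CONSENSUS_HOM_A, CONSENSUS_HOM_B, NON_CONSENSUS, UNINFORMATIVE)
_CODE = {label: i for i, label in enumerate(STATE_LABELS)}
_CONSENSUS_CODES = (0, 1)


@dataclass(frozen=True)
class GenotypeCounts:
    """Tallies of the four genotype classes for one SNP in one group."""

    n_hom_a: int
    n_het: int
    n_hom_b: int
    n_nocall: int

    @property
    def n_called(self) -> int:
        return self.n_hom_a + self.n_het + self.n_hom_b

    @property
    def total(self) -> int:
        return self.n_called + self.n_nocall


@dataclass(frozen=True)
class ConsensusState:
    """Per-SNP group state; ``top_frequency`` is None when uninformative."""

    state: str
    top_frequency: float | None


@dataclass(frozen=True)
class HomozygousRun:
    """A maximal stretch of consensus-homozygous SNPs in the case group.

    Indices are inclusive contiguous map indices; ``n_snps`` counts every SNP
    between the boundaries while ``n_informative`` counts consensus calls
    only (interior all-no-call SNPs are tolerated).  ``carrier_pass`` is True
    when carriers are not consensus-homozygous for the identical alleles
    across the run, False when they are, None when undetermined (no carriers).
    """

    chromosome: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_informative: int
    consensus_alleles: tuple[str, ...]
    carrier_pass: bool | None = None

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def genotype_counts(group: GenotypeMatrix, snp_index: int) -> GenotypeCounts:
    """Exact genotype tallies for one SNP in a group."""
    if not 0 <= snp_index < group.n_snps:
        raise IndexError(f"SNP index {snp_index} out of range 0..{group.n_snps - 1}")
    col = group.calls[:, snp_index]
    return GenotypeCounts(
        int((col == HOM_A).sum()),
        int((col == HET).sum()),
        int((col == HOM_B).sum()),
        int((col == NOCALL).sum()),
    )


def consensus_state(c: GenotypeCounts) -> ConsensusState:
    """Classify one SNP from its group tallies.

    The frequency denominator excludes no-calls; a SNP is consensus
    homozygous iff the top frequency is exactly 1 and the top genotype is a
    homozygote.  All-no-call SNPs are uninformative.
    """
    if c.n_called == 0:
        return ConsensusState(UNINFORMATIVE, None)
    top = max(c.n_hom_a, c.n_het, c.n_hom_b)
    freq = top / c.n_called
    if c.n_hom_a == c.n_called:
        return ConsensusState(CONSENSUS_HOM_A, freq)
    if c.n_hom_b == c.n_called:
        return ConsensusState(CONSENSUS_HOM_B, freq)
    return ConsensusState(NON_CONSENSUS, freq)


def group_states(group: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-SNP consensus codes and top frequencies for a group.

    Returns (codes, freqs) arrays over all SNPs; codes index STATE_LABELS
    and freqs is NaN where uninformative.
    """
    calls = group.calls
    a = (calls == HOM_A).sum(axis=0)
    h = (calls == HET).sum(axis=0)
    b = (calls == HOM_B).sum(axis=0)
    called = a + h + b
    codes = np.full(group.n_snps, _CODE[NON_CONSENSUS], dtype=np.int8)
    codes[called == 0] = _CODE[UNINFORMATIVE]
    codes[(called > 0) & (a == called)] = _CODE[CONSENSUS_HOM_A]
    codes[(called > 0) & (b == called)] = _CODE[CONSENSUS_HOM_B]
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.maximum(np.maximum(a, h), b) / called
    return codes, freqs


def _codes_from_states(states) -> np.ndarray:
    if isinstance(states, np.ndarray) and states.dtype != object:
        return states.astype(np.int8)
    out = np.empty(len(states), dtype=np.int8)
    for i, s in enumerate(states):
        label = s.state if isinstance(s, ConsensusState) else str(s)
        out[i] = _CODE[label]
    return out


def find_runs(
    states,
    snp_map: SnpMap,
    min_snps: int = 10,
    strict: bool = True,
) -> list[HomozygousRun]:
    """Extract all maximal qualifying consensus-homozygous runs.

    ``states`` is a per-SNP sequence of ConsensusState (or the code array
    from :func:`group_states`) aligned to ``snp_map``.  A run qualifies when
    its informative-SNP count is strictly greater than ``min_snps`` when
    ``strict`` (the Methods' "more than 10 SNPs") or at least ``min_snps``
    otherwise (the Discussion's "at least 10").  Runs never cross a
    chromosome boundary; the consensus allele may switch between homA and
    homB within one run (the criterion is per-SNP homozygosity, not a shared
    haplotype allele).
    """
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    codes = _codes_from_states(states)
    if len(codes) != len(snp_map):
        raise ValueError(f"{len(codes)} states for {len(snp_map)} map entries")
    positions = snp_map.positions
    runs: list[HomozygousRun] = []
    non = _CODE[NON_CONSENSUS]
    for chrom, lo, hi in snp_map.chrom_slices():
        block = codes[lo:hi]
        breaks = np.flatnonzero(block == non)
        edges = np.concatenate(([-1], breaks, [hi - lo]))
        for k in range(len(edges) - 1):
            s, e = int(edges[k]) + 1, int(edges[k + 1]) - 1  # inclusive, local
            if e < s:
                continue
            inf = np.flatnonzero(np.isin(block[s : e + 1], _CONSENSUS_CODES))
            if inf.size == 0:
                continue
            s2 = s + int(inf[0])
            e2 = s + int(inf[-1])
            n_informative = int(inf.size)
            qualifies = n_informative > min_snps if strict else n_informative >= min_snps
            if not qualifies:
                continue
            runs.append(
                HomozygousRun(
                    chromosome=chrom,
                    start_index=lo + s2,
                    end_index=lo + e2,
                    start_bp=int(positions[lo + s2]),
                    end_bp=int(positions[lo + e2]),
                    n_snps=e2 - s2 + 1,
                    n_informative=n_informative,
                    consensus_alleles=tuple(
                        STATE_LABELS[c] for c in block[s2 : e2 + 1]
                    ),
                )
            )
    return runs


def carrier_filter(run: HomozygousRun, carrier_states) -> HomozygousRun:
    """Re-check one run in the carrier group (region-level verdict).

    carrier_pass is False only when the carriers are consensus-homozygous
    for the *identical* allele at every informative SNP of the run — i.e.
    the region fails only if the carrier group looks exactly like the case
    group across the whole run.  ``carrier_states`` None (no carriers)
    leaves the verdict undetermined.
    """
    if carrier_states is None:
        return replace(run, carrier_pass=None)
    codes = _codes_from_states(carrier_states)
    all_same = True
    for offset, label in enumerate(run.consensus_alleles):
        aff_code = _CODE[label]
        if aff_code not in _CONSENSUS_CODES:
            continue  # interior uninformative SNP: not part of the criterion
        if codes[run.start_index + offset] != aff_code:
            all_same = False
            break
    return replace(run, carrier_pass=not all_same)


def scan(
    m: GenotypeMatrix,
    min_snps: int = 10,
    strict: bool = True,
) -> list[HomozygousRun]:
    """Whole-genome consensus scan: split by status, call consensus states on
    the affected group, extract runs, and re-check each in the carriers.

    Output is sorted largest first: by SNP count, then bp span, then genomic
    order.  The normal group plays no part in the scan.
    """
    affected, carrier, _ = split_by_status(m)
    codes, _freqs = group_states(affected)
    runs = find_runs(codes, m.snp_map, min_snps=min_snps, strict=strict)
    carrier_codes = group_states(carrier)[0] if carrier.n_samples > 0 else None
    runs = [carrier_filter(r, carrier_codes) for r in runs]
    runs.sort(
        key=lambda r: (
            -r.n_snps,
            -r.span_bp,
            chromosome_key(r.chromosome),
            r.start_bp,
        )
    )
    return runs
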