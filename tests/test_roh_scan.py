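"""Consensus-state calling, run extraction, carrier filter and full scan."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from amap.genotype_io import GenotypeMatrix, HET, HOM_A, HOM_B, NOCALL, SnpMap
from amap.roh_scan import (
    CONSENSUS_HOM_A,
    CONSENSUS_HOM_B,
    NON_CONSENSUS,
    UNINFORMATIVE,
    STATE_LABELS,
    ConsensusState,
    GenotypeCounts,
    carrier_filter,
    consensus_state,
    find_runs,
    genotype_counts,
    group_states,
    scan,
)

A, B, N, U = (STATE_LABELS.index(s) for s in STATE_LABELS)


def single_chrom_map(n, chrom="1"):
    return SnpMap.from_records([(f"s{i}", chrom, 100 * (i + 1)) for i in range(n)])


def states_map(codes, chroms=None):
    """Build (codes array, SnpMap) from state-code list; chroms optional
    parallel list to exercise chromosome boundaries."""
    codes = np.asarray(codes, dtype=np.int8)
    if chroms is None:
        snp_map = single_chrom_map(len(codes))
    else:
        records, seen = [], {}
        for i, c in enumerate(chroms):
            seen[c] = seen.get(c, 0) + 1
            records.append((f"s{i}", c, 100 * seen[c]))
        snp_map = SnpMap.from_records(records)
    return codes, snp_map


def exhaustive_window_oracle(codes, snp_map, min_snps, strict):
    """Independent run-finder: enumerate every window, keep valid maximal ones.

    A window is valid when it lies in one chromosome, contains no
    non-consensus SNP, has consensus SNPs at both boundaries, and its
    consensus count clears the threshold.  Maximal = not strictly contained
    in another valid window.
    """
    chroms = snp_map.chromosomes
    valid = []
    n = len(codes)
    for s in range(n):
        for e in range(s, n):
            if chroms[s] != chroms[e]:
                continue
            window = codes[s : e + 1]
            if (window == N).any():
                continue
            if codes[s] not in (A, B) or codes[e] not in (A, B):
                continue
            ninf = int(np.isin(window, (A, B)).sum())
            ok = ninf > min_snps if strict else ninf >= min_snps
            if ok:
                valid.append((s, e))
    maximal = [
        (s, e)
        for s, e in valid
        if not any((s2 <= s and e <= e2 and (s2, e2) != (s, e)) for s2, e2 in valid)
    ]
    return sorted(maximal)


class TestConsensusState:
    @pytest.mark.parametrize(
        "counts, state, freq",
        [
            ((17, 0, 0, 0), CONSENSUS_HOM_A, 1.0),
            ((16, 0, 0, 1), CONSENSUS_HOM_A, 1.0),  # no-call excluded from denominator
            ((16, 1, 0, 0), NON_CONSENSUS, 16 / 17),
            ((0, 0, 17, 0), CONSENSUS_HOM_B, 1.0),
            ((0, 17, 0, 0), NON_CONSENSUS, 1.0),  # all-het is not homozygous
            ((0, 0, 0, 17), UNINFORMATIVE, None),
        ],
    )
    def test_examples(self, counts, state, freq):
        result = consensus_state(GenotypeCounts(*counts))
        assert result.state == state
        if freq is None:
            assert result.top_frequency is None
        else:
            assert result.top_frequency == pytest.approx(freq)

    def test_genotype_counts_tally(self):
        calls = np.array([[HOM_A], [HOM_A], [HET], [NOCALL]], dtype=np.int8)
        m = GenotypeMatrix(
            ["a", "b", "c", "d"], ["affected"] * 4, calls, single_chrom_map(1)
        )
        assert genotype_counts(m, 0) == GenotypeCounts(2, 1, 0, 1)
        with pytest.raises(IndexError):
            genotype_counts(m, 1)

    def test_empty_group(self):
        m = GenotypeMatrix([], [], np.zeros((0, 1), np.int8), single_chrom_map(1))
        assert genotype_counts(m, 0) == GenotypeCounts(0, 0, 0, 0)
        assert consensus_state(genotype_counts(m, 0)).state == UNINFORMATIVE

    def test_group_states_matches_scalar_path(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 4, size=(6, 40)).astype(np.int8)
        m = GenotypeMatrix(
            [f"i{k}" for k in range(6)], ["affected"] * 6, calls, single_chrom_map(40)
        )
        codes, freqs = group_states(m)
        for j in range(40):
            expected = consensus_state(genotype_counts(m, j))
            assert STATE_LABELS[codes[j]] == expected.state


class TestFindRuns:
    def test_125_snp_stretch(self):
        codes, snp_map = states_map([N] + [A] * 125 + [N])
        runs = find_runs(codes, snp_map)
        assert len(runs) == 1
        assert runs[0].n_snps == 125
        assert (runs[0].start_index, runs[0].end_index) == (1, 125)

    def test_strict_threshold_at_exactly_ten(self):
        codes, snp_map = states_map([N] + [A] * 10 + [N])
        assert find_runs(codes, snp_map, min_snps=10, strict=True) == []
        relaxed = find_runs(codes, snp_map, min_snps=10, strict=False)
        assert len(relaxed) == 1 and relaxed[0].n_informative == 10

    def test_alternating_has_no_runs(self):
        codes, snp_map = states_map([A, N] * 10)
        assert find_runs(codes, snp_map, min_snps=2, strict=False) == []

    def test_uninformative_does_not_break_or_count(self):
        codes, snp_map = states_map([N, A, A, U, A, A, N])
        runs = find_runs(codes, snp_map, min_snps=4, strict=False)
        assert len(runs) == 1
        run = runs[0]
        assert (run.n_snps, run.n_informative) == (5, 4)
        # boundaries trimmed to informative SNPs
        assert (run.start_index, run.end_index) == (1, 5)

    def test_boundary_trimming_to_informative(self):
        codes, snp_map = states_map([U, A, A, A, U])
        runs = find_runs(codes, snp_map, min_snps=3, strict=False)
        assert (runs[0].start_index, runs[0].end_index) == (1, 3)
        assert runs[0].start_bp == 200 and runs[0].end_bp == 400

    def test_allele_switch_does_not_break_run(self):
        codes, snp_map = states_map([A, A, B, B])
        runs = find_runs(codes, snp_map, min_snps=4, strict=False)
        assert len(runs) == 1 and runs[0].n_informative == 4

    def test_runs_do_not_cross_chromosomes(self):
        codes, snp_map = states_map([A] * 6, chroms=["1"] * 3 + ["2"] * 3)
        runs = find_runs(codes, snp_map, min_snps=3, strict=False)
        assert [r.chromosome for r in runs] == ["1", "2"]

    def test_min_snps_below_one_raises(self):
        codes, snp_map = states_map([A, A])
        with pytest.raises(ValueError):
            find_runs(codes, snp_map, min_snps=0)

    def test_accepts_consensus_state_objects(self):
        snp_map = single_chrom_map(3)
        states = [
            ConsensusState(CONSENSUS_HOM_A, 1.0),
            ConsensusState(CONSENSUS_HOM_A, 1.0),
            ConsensusState(NON_CONSENSUS, 0.5),
        ]
        runs = find_runs(states, snp_map, min_snps=2, strict=False)
        assert len(runs) == 1 and runs[0].n_snps == 2

    @given(
        st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=60),
        st.integers(min_value=1, max_value=6),
        st.booleans(),
        st.integers(min_value=1, max_value=3),
    )
    def test_matches_exhaustive_window_oracle(self, codes, min_snps, strict, n_chrom):
        chroms = [str(1 + (i * n_chrom) // len(codes)) for i in range(len(codes))]
        arr, snp_map = states_map(codes, chroms=chroms)
        runs = find_runs(arr, snp_map, min_snps=min_snps, strict=strict)
        got = sorted((r.start_index, r.end_index) for r in runs)
        assert got == exhaustive_window_oracle(arr, snp_map, min_snps, strict)

    @given(
        st.lists(st.integers(min_value=0, max_value=3), min_size=1, max_size=50),
        st.integers(min_value=1, max_value=5),
    )
    def test_raising_threshold_never_adds_runs(self, codes, min_snps):
        arr, snp_map = states_map(codes)
        lower = {(r.start_index, r.end_index) for r in find_runs(arr, snp_map, min_snps)}
        higher = {
            (r.start_index, r.end_index) for r in find_runs(arr, snp_map, min_snps + 1)
        }
        assert higher <= lower


class TestCarrierFilter:
    def make_run(self, codes, snp_map, **kwargs):
        return find_runs(codes, snp_map, **kwargs)[0]

    def test_carrier_heterozygosity_passes(self):
        codes, snp_map = states_map([A] * 5)
        run = self.make_run(codes, snp_map, min_snps=5, strict=False)
        carrier = np.array([A, A, N, A, A], dtype=np.int8)
        assert carrier_filter(run, carrier).carrier_pass is True

    def test_identical_consensus_fails(self):
        codes, snp_map = states_map([A, A, B, A])
        run = self.make_run(codes, snp_map, min_snps=4, strict=False)
        assert carrier_filter(run, codes.copy()).carrier_pass is False

    def test_consensus_for_other_homozygote_passes(self):
        codes, snp_map = states_map([A] * 4)
        run = self.make_run(codes, snp_map, min_snps=4, strict=False)
        carrier = np.array([A, A, B, A], dtype=np.int8)
        assert carrier_filter(run, carrier).carrier_pass is True

    def test_no_carriers_undetermined(self):
        codes, snp_map = states_map([A] * 4)
        run = self.make_run(codes, snp_map, min_snps=4, strict=False)
        assert carrier_filter(run, None).carrier_pass is None

    def test_interior_uninformative_ignored(self):
        codes, snp_map = states_map([A, U, A])
        run = self.make_run(codes, snp_map, min_snps=2, strict=False)
        carrier = np.array([A, N, A], dtype=np.int8)
        assert carrier_filter(run, carrier).carrier_pass is False


class TestScan:
    def build_cohort(self, affected_rows, carrier_rows, chrom="1"):
        calls = np.array(affected_rows + carrier_rows, dtype=np.int8)
        snp_map = single_chrom_map(calls.shape[1], chrom)
        statuses = ["affected"] * len(affected_rows) + ["carrier"] * len(carrier_rows)
        return GenotypeMatrix(
            [f"i{k}" for k in range(calls.shape[0])], statuses, calls, snp_map
        )

    def test_scan_composition(self):
        aff = [[HOM_A] * 12 + [HET] + [HOM_B] * 12] * 3
        car = [[HET] * 25]
        m = self.build_cohort(aff, car)
        runs = scan(m, min_snps=10, strict=True)
        assert len(runs) == 2
        assert all(r.carrier_pass is True for r in runs)
        assert {(r.start_index, r.end_index) for r in runs} == {(0, 11), (13, 24)}

    def test_no_consensus_gives_empty(self):
        aff = [[HOM_A] * 20, [HET] * 20]
        m = self.build_cohort(aff, [])
        assert scan(m, min_snps=5, strict=False) == []

    def test_carrier_homozygous_region_flagged_not_dropped(self):
        aff = [[HOM_A] * 15] * 4
        car = [[HOM_A] * 15, [HOM_A] * 15]
        runs = scan(self.build_cohort(aff, car), min_snps=10, strict=True)
        assert len(runs) == 1 and runs[0].carrier_pass is False

    def test_sorted_largest_first(self):
        row = [HOM_A] * 30 + [HET] + [HOM_A] * 14 + [HET] + [HOM_A] * 20
        m = self.build_cohort([row, row], [])
        runs = scan(m, min_snps=10, strict=True)
        assert [r.n_snps for r in runs] == [30, 20, 14]

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 4, size=(8, 60)).astype(np.int8)
        statuses = ["affected"] * 5 + ["carrier"] * 3
        snp_map = single_chrom_map(60)
        m = GenotypeMatrix([f"i{k}" for k in range(8)], statuses, calls, snp_map)
        perm = rng.permutation(8)
        shuffled = m.subset_samples(list(perm))
        result = [
            (r.start_index, r.end_index, r.carrier_pass)
            for r in scan(m, min_snps=2, strict=False)
        ]
        assert result == [
            (r.start_index, r.end_index, r.carrier_pass)
            for r in scan(shuffled, min_snps=2, strict=False)
        ]

    def test_single_nocall_never_shortens_run(self):
        # no-calls are excluded from the frequency denominator, so masking
        # one called genotype of a non-boundary SNP keeps the run intact
        aff = [[HOM_A] * 14 + [HET]] * 4
        m = self.build_cohort(aff, [])
        baseline = scan(m, min_snps=10, strict=True)[0]
        for sample in range(4):
            for snp in range(1, 13):
                mutated = m.calls.copy()
                mutated[sample, snp] = NOCALL
                m2 = GenotypeMatrix(
                    list(m.sample_ids), list(m.statuses), mutated, m.snp_map
                )
                run = scan(m2, min_snps=10, strict=True)[0]
                assert run.n_snps >= baseline.n_snps
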