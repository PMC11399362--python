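"""Junction screening, even-site selection, probe assembly, quantity math."""

from itertools import permutations

import pytest
from hypothesis import given
from hypothesis import strategies as st

import circprobe as cp

DNA = st.text(alphabet="ACGT", min_size=1, max_size=120)


def make_site(seq, start, target_id="t"):
    return cp.CandidateSite(
        target_id=target_id,
        start=start,
        sequence=seq,
        gc_fraction=cp.gc_fraction(seq),
        tm_celsius=cp.melting_temperature(seq),
        max_homopolymer=cp.max_homopolymer_run(seq),
        host_clean=True,
        composition_pass=True,
    )


def sites_from(target, starts):
    return [make_site(target[s : s + 20], s) for s in starts]


@pytest.fixture(scope="module")
def target_400():
    rng = __import__("numpy").random.default_rng(42)
    return "".join(rng.choice(list("ACGT"), size=400))


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,rc", [("ACGT", "ACGT"), ("AAAA", "TTTT"), ("GGATC", "GATCC")]
    )
    def test_known_values(self, seq, rc):
        assert cp.reverse_complement(seq) == rc

    @given(DNA)
    def test_involution(self, seq):
        assert cp.reverse_complement(cp.reverse_complement(seq)) == seq

    def test_alphabet_error(self):
        with pytest.raises(cp.AlphabetError):
            cp.reverse_complement("ACGN")


class TestJunctions:
    def test_mode_all_checks_15_spanning_16mers(self, target_400):
        left, right = sites_from(target_400, [0, 100])
        idx = cp.HostIndex(backend="set")
        check = cp.junction_clean(idx, left, right, mode="all")
        assert len(check.checked_codes) == 15
        joined = left.sequence + right.sequence
        assert list(check.checked_codes) == [
            cp.encode_kmer(joined[s : s + 16]) for s in range(5, 20)
        ]
        assert check.clean

    def test_mode_center_checks_the_8_plus_8_16mer(self, target_400):
        left, right = sites_from(target_400, [0, 100])
        idx = cp.HostIndex(backend="set")
        check = cp.junction_clean(idx, left, right, mode="center")
        joined = left.sequence + right.sequence
        assert check.checked_codes == (cp.encode_kmer(joined[12:28]),)

    def test_boundary_16mer_in_host_fails_both_modes(self, target_400):
        left, right = sites_from(target_400, [0, 100])
        joined = left.sequence + right.sequence
        host = cp.NucSequence("h", joined[12:28])  # 8 bases each side
        idx = cp.build_host_index([host], backend="set")
        assert not cp.junction_clean(idx, left, right, mode="all").clean
        assert not cp.junction_clean(idx, left, right, mode="center").clean

    def test_off_center_spanning_16mer_caught_only_by_mode_all(self, target_400):
        left, right = sites_from(target_400, [0, 100])
        joined = left.sequence + right.sequence
        host = cp.NucSequence("h", joined[6:22])  # spans boundary at offset 20
        idx = cp.build_host_index([host], backend="set")
        assert not cp.junction_clean(idx, left, right, mode="all").clean
        assert cp.junction_clean(idx, left, right, mode="center").clean

    def test_junction_decision_matches_string_oracle(self, target_400):
        left, right = sites_from(target_400, [40, 200])
        joined = left.sequence + right.sequence
        host = cp.NucSequence("h", target_400[150:260])
        idx = cp.build_host_index([host], backend="set")
        windows = {
            host.residues[i : i + 16] for i in range(len(host.residues) - 15)
        }
        oracle = all(joined[s : s + 16] not in windows for s in range(5, 20))
        assert cp.junction_clean(idx, left, right, mode="all").clean == oracle


class TestAssembly:
    def test_probe_is_the_80nt_genomic_order_concatenation(self, target_400):
        idx = cp.HostIndex(backend="set")
        sites = sites_from(target_400, [10, 110, 210, 310])
        junctions = [
            cp.junction_clean(idx, sites[i], sites[(i + 1) % 4]) for i in range(4)
        ]
        design = cp.assemble_probe(sites, junctions)
        assert len(design.probe_sequence) == 80 == cp.PROBE_LENGTH
        assert design.probe_sequence == "".join(s.sequence for s in sites)
        assert cp.reverse_complement(design.probe_revcomp) == design.probe_sequence
        for site, rc in zip(design.sites, design.arm_revcomps):
            assert rc == cp.reverse_complement(site.sequence)

    def test_probe_revcomp_holds_arm_revcomps_in_reverse_order(self, target_400):
        idx = cp.HostIndex(backend="set")
        sites = sites_from(target_400, [10, 110, 210, 310])
        junctions = [
            cp.junction_clean(idx, sites[i], sites[(i + 1) % 4]) for i in range(4)
        ]
        design = cp.assemble_probe(sites, junctions)
        assert design.probe_revcomp == "".join(reversed(design.arm_revcomps))

    def test_dirty_junction_refuses_assembly(self, target_400):
        sites = sites_from(target_400, [10, 110, 210, 310])
        joined = sites[0].sequence + sites[1].sequence
        host = cp.NucSequence("h", joined[12:28])
        idx = cp.build_host_index([host], backend="set")
        junctions = [
            cp.junction_clean(idx, sites[i], sites[(i + 1) % 4]) for i in range(4)
        ]
        with pytest.raises(cp.DesignFailure):
            cp.assemble_probe(sites, junctions)

    def test_overlapping_sites_refused(self, target_400):
        idx = cp.HostIndex(backend="set")
        sites = sites_from(target_400, [10, 25, 210, 310])
        junctions = [
            cp.junction_clean(idx, sites[i], sites[(i + 1) % 4]) for i in range(4)
        ]
        with pytest.raises(cp.DesignFailure):
            cp.assemble_probe(sites, junctions)


def selection_oracle(sites, target_length, index, mode):
    """Exhaustive search: best feasible anchor assignment under the
    lexicographic (distance-to-anchor, start) key vector."""
    anchors = [((i + 0.5) / 4) * target_length for i in range(4)]
    best_key, best = None, None
    for combo in permutations(sites, 4):
        ok = all(
            abs(a.start - b.start) >= 20
            for i, a in enumerate(combo)
            for b in combo[i + 1 :]
        )
        if not ok:
            continue
        ordered = sorted(combo, key=lambda s: s.start)
        pairs = list(zip(ordered, ordered[1:])) + [(ordered[3], ordered[0])]
        if not all(
            cp.junction_clean(index, a, b, mode).clean for a, b in pairs
        ):
            continue
        key = tuple(
            (abs(s.center - a), s.start) for s, a in zip(combo, anchors)
        )
        if best_key is None or key < best_key:
            best_key, best = key, ordered
    return best


class TestSelection:
    def test_exactly_four_compatible_sites_are_chosen(self, target_400):
        idx = cp.HostIndex(backend="set")
        sites = sites_from(target_400, [5, 120, 240, 360])
        design = cp.select_even_sites(sites, 400, idx)
        assert [s.start for s in design.sites] == [5, 120, 240, 360]
        assert len(design.junctions) == 4
        assert all(j.clean for j in design.junctions)

    def test_three_sites_is_a_design_failure(self, target_400):
        idx = cp.HostIndex(backend="set")
        sites = sites_from(target_400, [5, 120, 240])
        with pytest.raises(cp.DesignFailure, match="valid candidate sites"):
            cp.select_even_sites(sites, 400, idx)

    def test_crowded_sites_cannot_form_a_quartet(self, target_400):
        idx = cp.HostIndex(backend="set")
        sites = sites_from(target_400, [5, 10, 15, 20, 25])
        with pytest.raises(cp.DesignFailure, match="non-overlapping"):
            cp.select_even_sites(sites, 400, idx)

    def test_matches_exhaustive_oracle(self, target_400):
        idx = cp.HostIndex(backend="set")
        starts = [3, 30, 55, 90, 140, 170, 230, 260, 330, 370]
        sites = sites_from(target_400, starts)
        design = cp.select_even_sites(sites, 400, idx)
        oracle = selection_oracle(sites, 400, idx, "all")
        assert [s.start for s in design.sites] == [s.start for s in oracle]

    def test_selection_is_deterministic(self, target_400):
        idx = cp.HostIndex(backend="set")
        sites = sites_from(target_400, [3, 30, 55, 90, 140, 170, 230, 260, 330, 370])
        a = cp.select_even_sites(sites, 400, idx)
        b = cp.select_even_sites(list(reversed(sites)), 400, idx)
        assert a.probe_sequence == b.probe_sequence

    def test_wraparound_junction_is_screened(self, target_400):
        # poison only the last->first boundary; with exactly 4 sites the
        # design must fail even though all internal junctions are clean
        sites = sites_from(target_400, [5, 120, 240, 360])
        joined = sites[3].sequence + sites[0].sequence
        host = cp.NucSequence("h", joined[12:28])
        idx = cp.build_host_index([host], backend="set")
        internal = [
            cp.junction_clean(idx, sites[i], sites[i + 1]) for i in range(3)
        ]
        assert all(j.clean for j in internal)
        with pytest.raises(cp.DesignFailure, match="junction"):
            cp.select_even_sites(sites, 400, idx)


class TestQuantities:
    def test_known_conversions(self):
        assert cp.moles_per_microliter(0.0, 80) == 0.0
        assert cp.moles_per_microliter(3.3, 100) == pytest.approx(0.1)
        assert cp.QuantInput(3.3, 100).moles_per_microliter() == pytest.approx(0.1)

    def test_zero_length_is_an_input_error(self):
        with pytest.raises(cp.InputError):
            cp.moles_per_microliter(1.0, 0)

    @given(
        st.floats(min_value=1e-3, max_value=1e3),
        st.integers(min_value=1, max_value=10_000),
    )
    def test_algebraic_inverse(self, conc, n_nt):
        pmol = cp.moles_per_microliter(conc, n_nt)
        back = pmol * n_nt * 330.0 * 1000.0 / 1e6
        assert back == pytest.approx(conc, rel=1e-12)
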