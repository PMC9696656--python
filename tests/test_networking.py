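"""Modified cosine, network pruning and MASST-style search."""

import itertools

import numpy as np
import pytest

from pepnetms import (
    Peak,
    Spectrum,
    build_fbmn_network,
    masst_prefilter,
    masst_search,
    modified_cosine,
)
from pepnetms.fixtures import generate_fixture_set
from pepnetms.simulate import SimulationConfig, simulate_spectrum
from pepnetms.peptides import parse_sequence_notation


def random_spectrum(rng, spec_id, n_peaks=None, mz_range=(100.0, 800.0)):
    n = n_peaks or int(rng.integers(5, 9))
    mzs = np.sort(rng.uniform(*mz_range, size=n))
    intensities = rng.uniform(0.1, 1.0, size=n)
    return Spectrum(
        id=spec_id,
        precursor_mz=float(rng.uniform(mz_range[1], mz_range[1] + 100)),
        peaks=tuple(Peak(float(m), float(i)) for m, i in zip(mzs, intensities)),
    )


def brute_force_pairing(a, b, frag_tol=0.02, allow_shift=True):
    """Exhaustive maximum-weight one-to-one pairing (oracle, <= 8 peaks)."""
    av = np.sqrt(a.intensity_array)
    bv = np.sqrt(b.intensity_array)
    av = av / np.linalg.norm(av)
    bv = bv / np.linalg.norm(bv)
    shift = a.precursor_mz - b.precursor_mz
    pairs = []
    for i, pa in enumerate(a.peaks):
        for j, pb in enumerate(b.peaks):
            d = pa.mz - pb.mz
            if abs(d) <= frag_tol or (allow_shift and abs(d - shift) <= frag_tol):
                pairs.append((i, j))

    best = 0.0
    best_n = 0
    for r in range(len(pairs), 0, -1):
        for combo in itertools.combinations(pairs, r):
            if len({i for i, _ in combo}) < r or len({j for _, j in combo}) < r:
                continue
            score = sum(av[i] * bv[j] for i, j in combo)
            if score > best + 1e-15:
                best, best_n = score, r
    return best, best_n


class TestModifiedCosine:
    def test_self_similarity(self, compound_a):
        sim = simulate_spectrum(compound_a, SimulationConfig(seed=3))
        cosine, matched = modified_cosine(sim.spectrum, sim.spectrum)
        assert cosine == pytest.approx(1.0, abs=1e-9)
        assert matched == len(sim.spectrum.peaks)

    def test_disjoint_spectra_score_zero(self):
        a = Spectrum("a", 500.0, peaks=(Peak(100.0, 1.0), Peak(200.0, 1.0)))
        b = Spectrum("b", 500.0, peaks=(Peak(150.0, 1.0), Peak(250.5, 1.0)))
        cosine, matched = modified_cosine(a, b)
        assert cosine == 0.0 and matched == 0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(1234)
        for k in range(50):
            a = random_spectrum(rng, f"a{k}")
            b = random_spectrum(rng, f"b{k}")
            ab = modified_cosine(a, b)
            ba = modified_cosine(b, a)
            assert ab[0] == pytest.approx(ba[0], abs=1e-9)
            assert ab[1] == ba[1]
            assert 0.0 <= ab[0] <= 1.0 + 1e-9

    def test_family_analogues_pass_published_thresholds(self):
        sims = generate_fixture_set(42, as_spectra=True)
        by_id = {s.id: s for s in sims}
        cosine, matched = modified_cosine(
            by_id["subarmigeride_A"], by_id["subarmigeride_B"], frag_tol=0.02
        )
        assert cosine >= 0.65 and matched > 6

    def test_greedy_equals_brute_force_on_small_spectra(self):
        """200 seeded random instances with <= 8 peaks: the greedy pairing
        attains the exhaustive maximum-weight matching."""
        rng = np.random.default_rng(99)
        for k in range(200):
            a = random_spectrum(rng, f"ga{k}")
            b = random_spectrum(rng, f"gb{k}")
            got = modified_cosine(a, b)
            want = brute_force_pairing(*(
                (a, b) if (a.id, a.precursor_mz) <= (b.id, b.precursor_mz) else (b, a)
            ))
            assert got[0] == pytest.approx(want[0], abs=1e-12)
            assert got[1] == want[1]

    def test_empty_rejected(self):
        a = Spectrum("a", 500.0, peaks=(Peak(100.0, 1.0),))
        empty = Spectrum("e", 500.0, peaks=())
        with pytest.raises(ValueError):
            modified_cosine(a, empty)

    def test_matches_matchms_modified_cosine(self):
        """Independent oracle: matchms's ModifiedCosine on the same
        sqrt-transformed peaks gives the same score and match count."""
        from matchms import Spectrum as MmsSpectrum
        from matchms.similarity import ModifiedCosine

        rng = np.random.default_rng(7)
        sims = generate_fixture_set(7, as_spectra=True)
        pairs = [(sims[0], sims[1]), (sims[0], sims[3]), (sims[4], sims[7])]
        for k in range(20):
            pairs.append(
                (random_spectrum(rng, f"ma{k}"), random_spectrum(rng, f"mb{k}"))
            )
        scorer = ModifiedCosine(tolerance=0.02)
        for a, b in pairs:
            ma = MmsSpectrum(
                mz=a.mz_array, intensities=np.sqrt(a.intensity_array),
                metadata={"precursor_mz": a.precursor_mz}, metadata_harmonization=False,
            )
            mb = MmsSpectrum(
                mz=b.mz_array, intensities=np.sqrt(b.intensity_array),
                metadata={"precursor_mz": b.precursor_mz}, metadata_harmonization=False,
            )
            res = scorer.pair(ma, mb)
            ours = modified_cosine(a, b, frag_tol=0.02)
            assert ours[0] == pytest.approx(float(res["score"]), abs=1e-6)
            assert ours[1] == int(res["matches"])


class TestNetwork:
    def test_family_forms_single_component(self):
        sims = generate_fixture_set(42, as_spectra=True)
        net = build_fbmn_network(sims)
        comps = net.components()
        assert len(comps) == 1 and len(comps[0]) == 8

    def test_unrelated_peptides_attach_no_edge(self):
        sims = generate_fixture_set(42, as_spectra=True)
        unrelated = [
            parse_sequence_notation(n)
            for n in (
                "H-Gly-Ala-Ser-Thr-Gly-Ala-OH",
                "H-Ser-Thr-Gly-Trp-His-Arg-OH",
                "H-Ala-Lys-Glu-Asp-Gly-Ser-Thr-OH",
            )
        ]
        others = [
            simulate_spectrum(p, SimulationConfig(seed=100 + i), f"unrelated_{i}").spectrum
            for i, p in enumerate(unrelated)
        ]
        net = build_fbmn_network(sims + others)
        family = {s.id for s in sims}
        for e in net.edges:
            assert (e.node_a in family) == (e.node_b in family)
        comps = net.components()
        assert family in comps

    def test_identical_pair_edge(self):
        sim = generate_fixture_set(1, as_spectra=True)[0]
        from dataclasses import replace

        twin = replace(sim, id="twin")
        net = build_fbmn_network([sim, twin])
        assert len(net.edges) == 1
        assert net.edges[0].cosine == pytest.approx(1.0, abs=1e-9)

    def test_every_edge_satisfies_thresholds(self):
        sims = generate_fixture_set(21, as_spectra=True)
        net = build_fbmn_network(sims, min_cosine=0.4, min_matched=5, top_k=3)
        for e in net.edges:
            assert e.cosine >= 0.4 and e.matched_peaks >= 5
        # mutual top-K audit
        for node in net.graph.nodes:
            assert net.graph.degree(node) <= 3

    def test_raising_cosine_threshold_only_removes_edges(self):
        sims = generate_fixture_set(42, as_spectra=True)
        loose = build_fbmn_network(sims, min_cosine=0.3)
        strict = build_fbmn_network(sims, min_cosine=0.8)
        loose_keys = {(e.node_a, e.node_b) for e in loose.edges}
        strict_keys = {(e.node_a, e.node_b) for e in strict.edges}
        assert strict_keys <= loose_keys


class TestMasst:
    def test_precursor_exclusion_window(self):
        s = Spectrum("s", 857.49, peaks=(Peak(850.0, 1.0), Peak(500.0, 1.0)))
        out = masst_prefilter(s)
        assert [p.mz for p in out.peaks] == [500.0]

    def test_windowed_top6(self):
        # 7 peaks within one 100 Da span: each peak's +/-50 Da window
        # contains all of them, so only the 6 most intense survive
        peaks = tuple(Peak(300.0 + 5 * i, float(i + 1)) for i in range(7))
        s = Spectrum("w", 1000.0, peaks=peaks)
        out = masst_prefilter(s)
        assert len(out.peaks) == 6
        assert min(p.intensity for p in out.peaks) == 2.0  # lowest dropped

    def test_idempotent_on_seeded_spectra(self):
        rng = np.random.default_rng(555)
        for k in range(100):
            s = random_spectrum(rng, f"i{k}", n_peaks=int(rng.integers(5, 40)))
            once = masst_prefilter(s)
            twice = masst_prefilter(once)
            assert once == twice

    def test_search_finds_only_the_true_analogue(self, compound_a):
        query = simulate_spectrum(compound_a, SimulationConfig(seed=31), "query").spectrum
        lib_a = simulate_spectrum(compound_a, SimulationConfig(seed=32), "lib_A").spectrum
        unrelated = simulate_spectrum(
            parse_sequence_notation("H-Gly-Ala-Ser-Thr-Gly-Ala-OH"),
            SimulationConfig(seed=33),
            "lib_other",
        ).spectrum
        matches = masst_search(query, [lib_a, unrelated])
        assert [m.library_id for m in matches] == ["lib_A"]
        assert matches[0].score > 0.2 and matches[0].matched_peaks >= 3

    def test_precursor_tolerance_gates_candidates(self, compound_a):
        query = simulate_spectrum(compound_a, SimulationConfig(seed=41), "q").spectrum
        from dataclasses import replace

        far = replace(query, id="far", precursor_mz=900.0)
        assert masst_search(query, [far]) == []

    def test_self_search_scores_one(self, compound_a):
        s = simulate_spectrum(compound_a, SimulationConfig(seed=51), "self").spectrum
        matches = masst_search(s, [s])
        assert len(matches) == 1
        assert matches[0].score == pytest.approx(1.0, abs=1e-9)
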