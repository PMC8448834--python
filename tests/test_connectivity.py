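import numpy as np
import pandas as pd
import pytest

from plsassay import (
    ConnectivityResult,
    GeneSet,
    PerturbationProfile,
    ProbeEntry,
    QuerySignature,
    SimulationConfig,
    attach_tau,
    collapse_probes,
    connectivity_score,
    extract_target_signature,
    ks_tag,
    random_query_background,
    select_candidates,
    simulate_perturbation_reference,
    tau_percentile,
)
from plsassay.connectivity import read_profiles, write_profiles

from _oracles import ks_brute_force


def profile_from_z(name, z_by_gene):
    entries = tuple(
        ProbeEntry(probe=f"{g}_p", gene=g, z=float(z)) for g, z in z_by_gene.items()
    )
    return PerturbationProfile(perturbagen=name, entries=entries)


class TestCollapseProbes:
    def test_landmark_beats_inferred_despite_lower_z(self):
        p = PerturbationProfile(
            "x",
            (
                ProbeEntry("p1", "A", 0.5, "landmark"),
                ProbeEntry("p2", "A", 3.0, "inferred"),
            ),
        )
        assert collapse_probes(p)["A"] == 0.5

    def test_highest_absolute_z_among_same_class(self):
        p = PerturbationProfile(
            "x",
            (
                ProbeEntry("p1", "A", -2.5, "inferred"),
                ProbeEntry("p2", "A", 1.0, "inferred"),
            ),
        )
        assert collapse_probes(p)["A"] == -2.5

    def test_single_probe_gene_unchanged(self):
        p = PerturbationProfile("x", (ProbeEntry("p1", "A", 1.7, "landmark"),))
        assert collapse_probes(p)["A"] == 1.7

    def test_tie_broken_by_probe_id(self):
        p = PerturbationProfile(
            "x",
            (
                ProbeEntry("pb", "A", 2.0, "landmark"),
                ProbeEntry("pa", "A", -2.0, "landmark"),
            ),
        )
        assert collapse_probes(p)["A"] == -2.0  # probe "pa" wins the tie


class TestExtractTargetSignature:
    def test_full_sized_sets(self):
        z = pd.Series(np.arange(500, dtype=float), index=[f"g{i:03d}" for i in range(500)])
        q = extract_target_signature(z, k=100)
        assert len(q.up) == 100 and len(q.down) == 100
        assert not set(q.up.genes) & set(q.down.genes)

    def test_short_profile_shrinks_k_to_avoid_overlap(self):
        z = pd.Series(np.arange(150, dtype=float), index=[f"g{i:03d}" for i in range(150)])
        q = extract_target_signature(z, k=100)
        assert len(q.up) == 75 and len(q.down) == 75
        assert not set(q.up.genes) & set(q.down.genes)

    def test_k_one_returns_argmax_and_argmin(self):
        z = pd.Series([0.3, 5.0, -2.0], index=["a", "b", "c"])
        q = extract_target_signature(z, k=1)
        assert q.up.genes == ("b",) and q.down.genes == ("c",)


class TestKsTag:
    def test_top_tags_closed_form(self):
        for n, t in [(50, 5), (100, 20), (10, 1)]:
            assert ks_tag(n, list(range(1, t + 1))) == pytest.approx(1 - t / n, abs=1e-15)

    def test_bottom_tags_mirror_closed_form(self):
        # tags at the bottom t positions: b peaks at j=1 with V_1 = n-t+1,
        # giving ks = -(1 - (t-1)/n)
        n, t = 50, 5
        expected = -(1 - (t - 1) / n)
        assert ks_tag(n, list(range(n - t + 1, n + 1))) == pytest.approx(expected, abs=1e-15)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(300):
            n = int(rng.integers(3, 100))
            t = int(rng.integers(1, min(20, n - 1) + 1))
            pos = sorted(rng.choice(np.arange(1, n + 1), size=t, replace=False).tolist())
            assert ks_tag(n, pos) == ks_brute_force(n, pos)

    def test_invalid_positions_rejected(self):
        with pytest.raises(ValueError):
            ks_tag(10, [3, 3, 5])
        with pytest.raises(ValueError):
            ks_tag(10, [0, 2])
        with pytest.raises(ValueError):
            ks_tag(10, list(range(1, 11)))  # t = n


class TestConnectivityScore:
    def _collection(self, seed=0, n_genes=120):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:03d}" for i in range(n_genes)]
        profiles = [
            profile_from_z(f"p{j}", dict(zip(genes, rng.normal(0, 1, n_genes))))
            for j in range(6)
        ]
        return genes, profiles

    def test_self_query_scores_plus_one_and_mirror_minus_one(self):
        genes, profiles = self._collection(seed=3)
        target = collapse_probes(profiles[0])
        mirrored = profile_from_z("mirror", (-target).to_dict())
        q = extract_target_signature(target, k=15)
        results = connectivity_score(profiles + [mirrored], q, n_perm=200, seed=0)
        by = {r.perturbagen: r for r in results}
        assert by["p0"].score == 1.0
        assert by["mirror"].score == -1.0

    def test_same_sign_ks_pair_gives_zero_s_raw(self):
        # tags for up and down both at the top -> both ks positive
        genes = [f"g{i:02d}" for i in range(40)]
        z = dict(zip(genes, np.arange(40, 0, -1, dtype=float)))
        prof = profile_from_z("p", z)
        q = QuerySignature(
            up=GeneSet("up", tuple(genes[:5])), down=GeneSet("down", tuple(genes[5:10]))
        )
        (r,) = connectivity_score([prof], q, n_perm=100, seed=0)
        assert r.s_raw == 0.0

    def test_scores_bounded_with_endpoint_attained(self):
        genes, profiles = self._collection(seed=4)
        q = extract_target_signature(collapse_probes(profiles[2]), k=12)
        results = connectivity_score(profiles, q, n_perm=100, seed=1)
        scores = np.array([r.score for r in results])
        assert (np.abs(scores) <= 1).all()
        assert np.isclose(np.abs(scores).max(), 1.0)

    def test_profile_without_query_genes_skipped(self, caplog):
        genes, profiles = self._collection(seed=5)
        orphan = profile_from_z("orphan", {"zzz1": 1.0, "zzz2": -1.0})
        q = extract_target_signature(collapse_probes(profiles[0]), k=10)
        with caplog.at_level("WARNING"):
            results = connectivity_score(profiles + [orphan], q, n_perm=100, seed=2)
        assert "orphan" not in {r.perturbagen for r in results}


class TestTau:
    def test_extreme_negative_score_maps_to_minus_100(self):
        assert tau_percentile(-0.9, [0.1, 0.5, -0.3]) == -100.0

    def test_zero_score_maps_to_zero(self):
        assert tau_percentile(0.0, [0.1, 0.5]) == 0.0

    def test_median_magnitude_maps_near_50(self):
        bg = np.linspace(-1, 1, 201)  # |bg| has median 0.5
        tau = tau_percentile(0.5, bg)
        assert abs(tau) == pytest.approx(50, abs=100 / len(bg) + 0.5)

    def test_antisymmetric_under_profile_sign_flip(self):
        rng = np.random.default_rng(6)
        bg = np.abs(rng.normal(0, 0.3, 500))
        bg = np.concatenate([bg, -bg])  # sign-symmetric background
        s = 0.21
        assert tau_percentile(-s, bg) == -tau_percentile(s, bg)


class TestSelection:
    def test_lincs_threshold(self):
        results = [
            ConnectivityResult("a", 0, 0, 0, score=-0.9, p_perm=0.5, tau=-95.0),
            ConnectivityResult("b", 0, 0, 0, score=-0.9, p_perm=0.5, tau=-50.0),
            ConnectivityResult("c", 0, 0, 0, score=0.9, p_perm=0.5, tau=20.0),
        ]
        assert select_candidates(results, "lincs") == ["a"]

    def test_cmap_requires_negative_score_and_small_p(self):
        hit = ConnectivityResult("a", 0, 0, 0, score=-0.8, p_perm=0.01, tau=0)
        weak_p = ConnectivityResult("b", 0, 0, 0, score=-0.8, p_perm=0.2, tau=0)
        pos = ConnectivityResult("c", 0, 0, 0, score=0.8, p_perm=0.01, tau=0)
        assert select_candidates([hit, weak_p, pos], "cmap") == ["a"]


class TestPlantedReverserRecovery:
    def test_reverser_attains_minimum_tau(self):
        hits = 0
        for seed in range(10):
            profiles, truth = simulate_perturbation_reference(SimulationConfig(seed=seed))
            q = QuerySignature(
                up=GeneSet("up", tuple(truth["poor_genes"])),
                down=GeneSet("down", tuple(truth["good_genes"])),
            )
            results = connectivity_score(profiles, q, n_perm=200, seed=seed)
            bg = random_query_background(profiles, len(q.up), len(q.down),
                                         n_queries=300, seed=seed + 1)
            attach_tau(results, bg)
            taus = {r.perturbagen: r.tau for r in results}
            if taus[truth["reverser"]] == min(taus.values()):
                hits += 1
        assert hits >= 9


class TestProfileIO:
    def test_tsv_round_trip(self, tmp_path):
        profiles, _ = simulate_perturbation_reference(SimulationConfig(seed=2))
        p = tmp_path / "profiles.tsv"
        write_profiles(profiles[:2], p)
        back = read_profiles(p)
        assert [b.perturbagen for b in back] == [x.perturbagen for x in profiles[:2]]
        assert back[0].entries == profiles[0].entries
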