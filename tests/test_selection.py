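import numpy as np
import pandas as pd
import pytest

from splitmr import (
    InstrumentSet,
    apply_strategy,
    clump,
    match_loci_across_iterations,
    select_significant,
)
from splitmr.exceptions import ClumpingError
from splitmr.selection import LocusRegistry, RegistryLocus


def _assoc_frame(pvalues, positions=None, chrom="1"):
    m = len(pvalues)
    positions = positions if positions is not None else [1 + 2_000_000 * j for j in range(m)]
    return pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chromosome": chrom,
            "position": positions,
            "pvalue": pvalues,
        }
    )


class TestSelectSignificant:
    def test_threshold_comparison(self):
        assocs = _assoc_frame([6e-8, 4e-8, 1e-7])
        assert select_significant(assocs, 5e-8) == ["v1"]

    def test_strict_subset_of_primary(self):
        rng = np.random.default_rng(4)
        assocs = _assoc_frame(10 ** -rng.uniform(5, 14, 30))
        primary = select_significant(assocs, 5e-8)
        strict = select_significant(assocs, 5e-11)
        assert set(strict) <= set(primary)

    def test_all_nonsignificant_gives_empty(self):
        assocs = _assoc_frame([1.0, 1.0, 1.0])
        assert select_significant(assocs, 5e-8) == []

    def test_ordered_by_pvalue(self):
        assocs = _assoc_frame([1e-9, 1e-12, 1e-10])
        assert select_significant(assocs, 5e-8) == ["v1", "v2", "v0"]


def _independent_reference(n, m, seed=0):
    rng = np.random.default_rng(seed)
    return rng.binomial(2, 0.3, size=(n, m)).astype(float)


class TestClump:
    def test_distant_uncorrelated_candidates_stay_separate(self):
        cands = _assoc_frame([1e-9, 1e-10], positions=[1, 1_500_001])
        ref = _independent_reference(500, 2)
        loci = clump(cands, ref, ["v0", "v1"])
        assert len(loci) == 2

    def test_close_candidates_merge_under_smallest_p(self):
        cands = pd.DataFrame(
            {
                "variant_id": ["a", "b"],
                "chromosome": "1",
                "position": [1, 500_001],
                "pvalue": [1e-9, 1e-10],
            }
        )
        ref = _independent_reference(500, 2, seed=1)
        loci = clump(cands, ref, ["a", "b"])
        assert len(loci) == 1
        assert loci[0].lead_variant == "b"  # p = 1e-10 wins
        assert loci[0].member_variants == {"a", "b"}

    def test_correlated_distant_candidates_merge(self):
        rng = np.random.default_rng(2)
        g0 = rng.binomial(2, 0.3, 2000).astype(float)
        noise = rng.binomial(1, 0.02, 2000)
        g1 = np.clip(g0 + noise - rng.binomial(1, 0.02, 2000), 0, 2)  # r2 >> 0.01
        cands = pd.DataFrame(
            {
                "variant_id": ["a", "b"],
                "chromosome": "1",
                "position": [1, 5_000_001],
                "pvalue": [1e-12, 1e-9],
            }
        )
        loci = clump(cands, np.column_stack([g0, g1]), ["a", "b"])
        assert len(loci) == 1
        assert loci[0].lead_variant == "a"

    def test_matches_brute_force_greedy_oracle(self):
        rng = np.random.default_rng(11)
        m = 20
        ref = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(800, m)).astype(float)
        # make a few columns correlated
        ref[:, 5] = np.clip(ref[:, 3] + rng.binomial(1, 0.05, 800), 0, 2)
        ref[:, 12] = np.clip(ref[:, 10] - rng.binomial(1, 0.05, 800), 0, 2)
        positions = np.sort(rng.choice(np.arange(1, 30_000_000, 1000), m, replace=False))
        cands = pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(m)],
                "chromosome": "1",
                "position": positions,
                "pvalue": 10 ** -rng.uniform(8, 20, m),
            }
        )
        loci = clump(cands, ref, list(cands["variant_id"]), 1_000_000, 0.01)
        # brute-force greedy oracle: plain python re-derivation of the lead set
        order = cands.sort_values("pvalue").reset_index(drop=True)
        col = {v: j for j, v in enumerate(cands["variant_id"])}
        leads = []
        for row in order.itertuples():
            blocked = False
            for lead_id, lead_pos in leads:
                r = np.corrcoef(ref[:, col[row.variant_id]], ref[:, col[lead_id]])[0, 1]
                if abs(row.position - lead_pos) < 1_000_000 or r**2 >= 0.01:
                    blocked = True
                    break
            if not blocked:
                leads.append((row.variant_id, row.position))
        assert [l.lead_variant for l in loci] == [v for v, _ in leads]

    def test_missing_reference_genotypes_reported(self):
        cands = _assoc_frame([1e-9])
        with pytest.raises(ClumpingError, match="v0"):
            clump(cands, _independent_reference(100, 1), ["other"])

    def test_empty_candidates_rejected(self):
        with pytest.raises(ClumpingError):
            clump(_assoc_frame([]), _independent_reference(10, 0), [])

    def test_lead_pairwise_constraint_holds(self, small_study, small_cohort):
        # every retained pair of leads is >= 1 Mb apart AND has r2 < 0.01,
        # with r2 estimated in the discovery group of that iteration
        for result in small_study.usable_iterations:
            iset = result.instrument_set
            stats = iset.lead_stats.set_index("variant_id")
            idx_a = result.split.indices("A")
            for i, a in enumerate(iset.lead_variants):
                for b in iset.lead_variants[i + 1 :]:
                    distance = abs(
                        int(stats.loc[a, "position"]) - int(stats.loc[b, "position"])
                    )
                    ga = small_cohort.genotypes[idx_a, small_cohort.variant_index(a)]
                    gb = small_cohort.genotypes[idx_a, small_cohort.variant_index(b)]
                    r2 = np.corrcoef(ga.astype(float), gb.astype(float))[0, 1] ** 2
                    assert distance >= 1_000_000
                    assert r2 < 0.01

    def test_clump_deterministic(self, rng):
        m = 15
        ref = rng.binomial(2, 0.3, size=(400, m)).astype(float)
        cands = pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(m)],
                "chromosome": "1",
                "position": np.arange(1, m * 400_000, 400_000)[:m],
                "pvalue": 10 ** -rng.uniform(8, 15, m),
            }
        )
        first = clump(cands, ref, list(cands["variant_id"]))
        second = clump(cands, ref, list(cands["variant_id"]))
        assert [l.lead_variant for l in first] == [l.lead_variant for l in second]
        assert [l.member_variants for l in first] == [l.member_variants for l in second]


def _simple_set(iteration, leads, positions, pvals):
    stats = pd.DataFrame(
        {
            "variant_id": leads,
            "chromosome": "1",
            "position": positions,
            "beta": 0.1,
            "se": 0.02,
            "z": 5.0,
            "pvalue": pvals,
        }
    )
    from splitmr.selection import Locus

    loci = [
        Locus(f"locus_{v}", v, {v}, "1", (p, p)) for v, p in zip(leads, positions)
    ]
    return InstrumentSet(iteration, "primary", 5e-8, loci, list(leads), stats)


class TestRegistry:
    def test_single_variant_all_iterations(self):
        sets = [_simple_set(k, ["v1"], [100], [1e-9]) for k in range(10)]
        registry = match_loci_across_iterations(sets, {"v1": ("1", 100)})
        assert len(registry.loci) == 1
        assert registry.loci[0].n_iterations_selected == 10

    def test_nearby_variants_merge_counts_union(self):
        pos = {"a": ("1", 100), "b": ("1", 200_100)}
        sets = [_simple_set(0, ["a"], [100], [1e-9]), _simple_set(1, ["b"], [200_100], [1e-9])]
        registry = match_loci_across_iterations(sets, pos)
        assert len(registry.loci) == 1
        assert registry.loci[0].n_iterations_selected == 2

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(3)
        n_var = 30
        positions = {
            f"v{j}": ("1", int(p))
            for j, p in enumerate(np.sort(rng.choice(np.arange(1, 40_000_000, 1000), n_var, False)))
        }
        sets = []
        for k in range(50):
            chosen = sorted(rng.choice(n_var, size=rng.integers(1, 6), replace=False))
            leads = [f"v{j}" for j in chosen]
            sets.append(
                _simple_set(k, leads, [positions[v][1] for v in leads], [1e-9] * len(leads))
            )
        registry = match_loci_across_iterations(sets, positions)
        # union-find oracle over all selected variants
        selected = sorted({v for s in sets for v in s.lead_variants})
        parent = {v: v for v in selected}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        for a in selected:
            for b in selected:
                if a < b and abs(positions[a][1] - positions[b][1]) < 1_000_000:
                    parent[find(a)] = find(b)
        groups = {}
        for v in selected:
            groups.setdefault(find(v), set()).add(v)
        oracle_counts = sorted(
            len({s.iteration for s in sets if set(s.lead_variants) & g})
            for g in groups.values()
        )
        ours = sorted(l.n_iterations_selected for l in registry.loci)
        assert ours == oracle_counts
        our_groups = sorted((sorted(l.members) for l in registry.loci))
        oracle_groups = sorted((sorted(g) for g in groups.values()))
        assert our_groups == oracle_groups


class TestStrategies:
    def _registry(self, counts, n_iter=100):
        loci = [
            RegistryLocus(f"cl_{i}", "1", {f"lead{i}"}, c, 1e-12, set(range(c)))
            for i, c in enumerate(counts)
        ]
        return LocusRegistry(loci, 1_000_000, n_iter)

    def test_primary_is_identity(self):
        iset = _simple_set(0, ["lead0"], [100], [1e-9])
        assert apply_strategy("primary", None, iset) is iset

    def test_no_full_replication_removes_always_selected(self):
        registry = self._registry([100, 40, 7])
        leads = ["lead0", "lead1", "lead2"]
        iset = _simple_set(0, leads, [100, 2_000_100, 4_000_100], [1e-12, 1e-9, 1e-10])
        out = apply_strategy("no_full_replication", registry, iset)
        assert out.lead_variants == ["lead1", "lead2"]

    def test_no_full_replication_requires_registry(self):
        iset = _simple_set(0, ["lead0"], [100], [1e-9])
        with pytest.raises(ValueError, match="registry"):
            apply_strategy("no_full_replication", None, iset)

    def test_strict_nested_in_primary(self):
        iset = _simple_set(
            0, ["a", "b", "c"], [100, 2_000_100, 4_000_100], [1e-12, 4e-11, 1e-9]
        )
        out = apply_strategy("strict", None, iset)
        assert out.lead_variants == ["a", "b"]
        assert set(out.lead_variants) <= set(iset.lead_variants)
        assert out.threshold == 5e-11

    def test_unknown_strategy_rejected(self):
        iset = _simple_set(0, ["a"], [100], [1e-9])
        with pytest.raises(ValueError):
            apply_strategy("bogus", None, iset)
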