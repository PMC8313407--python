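"""Editing-site frequency folding, filter cascade, clustering, ECRs, pooling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ecrscan.core import GenomicInterval, PipelineParams, ValidationError
from ecrscan.editing import (
    EditingCluster,
    SiteTable,
    average_editing,
    build_ecrs,
    cluster_site_table,
    cluster_sites,
    compute_site_frequency,
    finalize_clusters,
    primary_site_filter,
    reporting_site_mask,
    secondary_site_filter,
)


class TestSiteFrequency:
    def test_sense_error_folding(self):
        ref, edit, freq = compute_site_frequency({"A": 80, "G": 10, "T": 5, "C": 5}, "+")
        assert (ref, edit) == (90, 10)
        assert freq == pytest.approx(0.10)

    def test_antisense_error_folding(self):
        ref, edit, freq = compute_site_frequency({"T": 90, "C": 10, "A": 0, "G": 0}, "-")
        assert (ref, edit) == (90, 10)
        assert freq == pytest.approx(0.10)

    def test_all_zero_counts_give_zero_frequency(self):
        _, _, freq = compute_site_frequency({"A": 0, "C": 0, "G": 0, "T": 0}, "+")
        assert freq == 0.0

    def test_unstranded_rejected(self):
        with pytest.raises(ValidationError):
            compute_site_frequency({"A": 1, "C": 0, "G": 0, "T": 0}, ".")


def make_table(rows, samples):
    """rows: list of dicts with pos and per-sample (edit, ref, score, pass)."""
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * len(rows),
            "pos": [r["pos"] for r in rows],
            "strand": [r.get("strand", "+") for r in rows],
            "snp": [r.get("snp", False) for r in rows],
        }
    )
    frames = {}
    for key, default in (("edit", 0.0), ("ref", 0.0), ("score", 1.0), ("passed", True)):
        frames[key] = pd.DataFrame(
            {s: [r.get(f"{key}_{s}", default) for r in rows] for s in samples}
        )
    return SiteTable(sites, frames["edit"], frames["ref"], frames["score"],
                     frames["passed"])


FREQS = [0.049, 0.05, 0.10, 0.95, 0.951]
READS = [9, 10]


class TestPrimaryFilter:
    def test_truth_table_on_boundary_grid(self, params):
        """Exhaustive grid over boundary frequencies/coverages × caller
        state × SNP flag reproduces the clause logic."""
        rows, expected = [], []
        pos = 0
        for f, n, passed, score, snp in itertools.product(
            FREQS, READS, [True, False], [0.49, 0.5], [False, True]
        ):
            rows.append(
                {
                    "pos": pos,
                    "snp": snp,
                    "edit_wt": f * n,
                    "ref_wt": (1 - f) * n,
                    "score_wt": score,
                    "passed_wt": passed,
                }
            )
            expected.append(
                (not snp) and passed and score >= 0.5 and n >= 10 and 0.05 <= f <= 0.95
            )
            pos += 1000
        table = make_table(rows, ["wt"])
        kept = primary_site_filter(table, ["wt"], params)
        kept_pos = set(kept.sites["pos"])
        for r, e in zip(rows, expected):
            assert (r["pos"] in kept_pos) == e, r

    def test_any_wt_sample_suffices(self, params):
        rows = [
            {"pos": 0, "edit_a": 1, "ref_a": 9, "score_a": 0.4,
             "edit_b": 2, "ref_b": 18, "score_b": 0.6},
        ]
        table = make_table(rows, ["a", "b"])
        assert len(primary_site_filter(table, ["a", "b"], params).sites) == 1
        assert len(primary_site_filter(table, ["a"], params).sites) == 0

    def test_empty_wt_rejected(self, params):
        table = make_table([{"pos": 0}], ["a"])
        with pytest.raises(ValidationError):
            primary_site_filter(table, [], params)


class TestSecondaryFilter:
    def _site(self, freqs, reads, samples):
        return {
            "pos": 0,
            **{f"edit_{s}": f * n for s, f, n in zip(samples, freqs, reads)},
            **{f"ref_{s}": (1 - f) * n for s, f, n in zip(samples, freqs, reads)},
        }

    def test_quoted_examples(self, params):
        samples = ["t1", "t2", "t3"]
        treatments = {"T": samples}
        ok = make_table(
            [self._site((0.06, 0.12, 0.15), (12, 30, 11), samples)], samples
        )
        assert len(secondary_site_filter(ok, treatments, params).sites) == 1
        low = make_table(
            [self._site((0.06, 0.08, 0.09), (20, 20, 20), samples)], samples
        )
        assert len(secondary_site_filter(low, treatments, params).sites) == 0
        missing = make_table(
            [self._site((0.12, 0.15, 0.0), (30, 11, 0), samples)], samples
        )
        assert len(secondary_site_filter(missing, treatments, params).sites) == 0

    def test_exhaustive_triplet_grid(self, params):
        """All 5^3 × 2 boundary combinations against the clause oracle."""
        samples = ["t1", "t2", "t3"]
        rows, expected = [], []
        pos = 0
        for fs in itertools.product(FREQS, repeat=3):
            for n in READS:
                rows.append(
                    {
                        "pos": pos,
                        **{f"edit_{s}": f * n for s, f in zip(samples, fs)},
                        **{f"ref_{s}": (1 - f) * n for s, f in zip(samples, fs)},
                    }
                )
                expected.append(
                    min(fs) >= 0.05
                    and sum(f >= 0.10 for f in fs) >= 2
                    and n >= 10
                )
                pos += 1000
        table = make_table(rows, samples)
        kept = set(
            secondary_site_filter(table, {"T": samples}, params).sites["pos"]
        )
        for r, e in zip(rows, expected):
            assert (r["pos"] in kept) == e, r

    def test_any_treatment_suffices(self, params):
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        row = {
            "pos": 0,
            **{f"edit_{s}": 0 for s in samples[:3]},
            **{f"ref_{s}": 0 for s in samples[:3]},
            **{f"edit_{s}": 5 for s in samples[3:]},
            **{f"ref_{s}": 20 for s in samples[3:]},
        }
        table = make_table([row], samples)
        treatments = {"A": samples[:3], "B": samples[3:]}
        assert len(secondary_site_filter(table, treatments, params).sites) == 1

    def test_triplet_size_enforced(self, params):
        table = make_table([{"pos": 0}], ["a", "b"])
        with pytest.raises(ValidationError):
            secondary_site_filter(table, {"T": ["a", "b"]}, params)


def oracle_clusters(positions, max_gap):
    """O(n^2) transitive closure of the pairwise gap <= max_gap relation."""
    positions = sorted(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())


class TestClustering:
    def test_worked_example(self):
        assert cluster_sites([100, 140, 190, 250], 50) == [[100, 140, 190], [250]]

    def test_gap_exactly_max_gap_joins(self):
        assert cluster_sites([100, 150], 50) == [[100, 150]]

    def test_singleton(self):
        assert cluster_sites([42], 50) == [[42]]

    def test_empty(self):
        assert cluster_sites([], 50) == []

    @given(
        positions=st.lists(
            st.integers(min_value=0, max_value=5000), min_size=1, max_size=60,
            unique=True,
        ),
        max_gap=st.integers(min_value=1, max_value=120),
    )
    def test_matches_transitive_closure_oracle(self, positions, max_gap):
        assert cluster_sites(positions, max_gap) == oracle_clusters(positions, max_gap)


class TestFinalizeClusters:
    def test_five_site_threshold(self, params):
        rows = [{"pos": p} for p in [0, 40, 80, 120, 160]]  # 5 sites
        rows += [{"pos": p} for p in [1000, 1040, 1080, 1120]]  # 4 sites
        table = make_table(rows, ["s"])
        final, clusters = finalize_clusters(table, params)
        assert len(clusters) == 1
        assert clusters[0].n_sites == 5
        assert set(final.sites["pos"]) == {0, 40, 80, 120, 160}

    def test_removed_bridge_splits_cluster(self, params):
        # two 3-site runs whose bridge was filtered out earlier: both dropped
        positions = [0, 40, 80, 160, 200, 240]  # gap 80 in the middle
        table = make_table([{"pos": p} for p in positions], ["s"])
        final, clusters = finalize_clusters(table, params)
        assert clusters == []
        assert len(final.sites) == 0

    def test_empty_input(self, params):
        table = make_table([], ["s"])
        final, clusters = finalize_clusters(table, params)
        assert clusters == [] and len(final.sites) == 0


class TestBuildEcrs:
    def _cluster(self, start, end):
        return EditingCluster("chr1", "+", (start, end - 1))

    def test_merge_below_2kb(self, params):
        ecrs = build_ecrs([self._cluster(5000, 5100), self._cluster(6500, 6600)], params)
        assert len(ecrs) == 1
        assert (ecrs[0].interval.start, ecrs[0].interval.end) == (4000, 7600)
        assert ecrs[0].n_clusters == 2

    def test_gap_exactly_2kb_stays_split(self, params):
        ecrs = build_ecrs([self._cluster(1000, 1100), self._cluster(3100, 3200)], params)
        assert len(ecrs) == 2
        assert (ecrs[0].interval.start, ecrs[0].interval.end) == (0, 2100)
        assert (ecrs[1].interval.start, ecrs[1].interval.end) == (2100, 4200)

    def test_pad_clamped_at_zero(self, params):
        ecrs = build_ecrs([self._cluster(300, 400)], params)
        assert ecrs[0].interval.start == 0

    def test_partition_matches_gap_graph(self, params):
        """ECR count equals connected components of the gap<2*pad graph, and
        every cluster belongs to exactly one ECR."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            starts = np.sort(rng.choice(50_000, size=12, replace=False))
            clusters = [self._cluster(int(s), int(s) + 50) for s in starts]
            ecrs = build_ecrs(clusters, params)
            seen = [c for e in ecrs for c in e.clusters]
            assert len(seen) == len(clusters)
            # oracle: chain gaps < 2000
            comps = 1
            for a, b in zip(clusters[:-1], clusters[1:]):
                if b.interval.start - a.interval.end >= 2 * params.ecr_pad:
                    comps += 1
            assert len(ecrs) == comps


class TestAverageEditing:
    def test_pooled_ratio(self):
        table = make_table(
            [{"pos": 0, "edit_s": 5, "ref_s": 45},
             {"pos": 100, "edit_s": 10, "ref_s": 40}],
            ["s"],
        )
        out = average_editing(table, {"g": [(0, "s"), (1, "s")]})
        assert out.loc[0, "editing"] == pytest.approx(0.15)

    def test_pooled_not_mean_of_ratios(self):
        table = make_table(
            [{"pos": 0, "edit_s": 1, "ref_s": 9},
             {"pos": 100, "edit_s": 50, "ref_s": 50}],
            ["s"],
        )
        out = average_editing(table, {"g": [(0, "s"), (1, "s")]})
        assert out.loc[0, "editing"] == pytest.approx(51 / 110)
        assert out.loc[0, "editing"] != pytest.approx(0.30)

    def test_zero_reads_flagged(self):
        table = make_table([{"pos": 0, "edit_s": 0, "ref_s": 0}], ["s"])
        out = average_editing(table, {"g": [(0, "s")]})
        assert out.loc[0, "editing"] == 0.0
        assert bool(out.loc[0, "no_reads"])

    def test_duplicate_assignment_rejected(self):
        table = make_table([{"pos": 0, "edit_s": 1, "ref_s": 9}], ["s"])
        with pytest.raises(ValidationError):
            average_editing(table, {"g": [(0, "s")], "h": [(0, "s")]})


class TestFilterMonotonicity:
    def test_tightening_never_grows_retained_set(self, params):
        rng = np.random.default_rng(5)
        samples = ["a1", "a2", "a3"]
        rows = []
        for pos in range(0, 40_000, 200):
            row = {"pos": pos, "snp": rng.random() < 0.1}
            for s in samples:
                n = int(rng.integers(0, 40))
                f = float(rng.random())
                row[f"edit_{s}"] = round(f * n)
                row[f"ref_{s}"] = n - round(f * n)
                row[f"score_{s}"] = float(rng.random())
                row[f"passed_{s}"] = bool(rng.random() < 0.8)
            rows.append(row)
        table = make_table(rows, samples)
        base_primary = set(
            primary_site_filter(table, samples, params).sites["pos"]
        )
        base_secondary = set(
            secondary_site_filter(table, {"T": samples}, params).sites["pos"]
        )
        tighter = [
            params.override(min_coverage=15),
            params.override(min_caller_score=0.7),
            params.override(freq_min=0.10, freq_high=0.15),
            params.override(freq_max=0.80),
        ]
        for tp in tighter:
            assert set(
                primary_site_filter(table, samples, tp).sites["pos"]
            ) <= base_primary
            assert set(
                secondary_site_filter(table, {"T": samples}, tp).sites["pos"]
            ) <= base_secondary

    def test_reporting_mask_never_alters_retained_set(self, params):
        samples = ["a", "b"]
        table = make_table(
            [{"pos": 0, "edit_a": 5, "ref_a": 10, "edit_b": 1, "ref_b": 2},
             {"pos": 100, "edit_a": 5, "ref_a": 10, "edit_b": 5, "ref_b": 10}],
            samples,
        )
        mask = reporting_site_mask(table, samples, min_reads=10)
        assert list(mask) == [False, True]
        # the table itself is untouched
        assert len(table.sites) == 2
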