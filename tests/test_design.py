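"""Design search: geometry enumeration, degeneracy application, ranking."""

import numpy as np
import pytest

from lampsmith import synth
from lampsmith.alignment import AlignmentSet, NonTargetIndex, column_profiles
from lampsmith.design import (
    GeometryConstraints,
    ScoreWeights,
    SearchLimits,
    apply_degeneracy,
    enumerate_candidates,
    score_candidate,
    search,
    validate_candidate_geometry,
)


def _aln(seqs, role="target", name="aln"):
    return AlignmentSet(name=name, role=role,
                        ids=[f"s{i}" for i in range(len(seqs))], sequences=seqs)


def _naive_geometry_check(candidate, constraints):
    """Independent re-validation written from the constraint definitions."""
    r = candidate.regions
    order = ["F3", "F2", "F1", "B1", "B2", "B3"]
    spans = [r[n].span for n in order]
    ok = all(e1 <= s2 for (_, e1), (s2, _) in zip(spans, spans[1:]))
    for name, region in r.items():
        lo, hi = constraints.region_lengths[name]
        ok &= lo <= region.span[1] - region.span[0] <= hi
    for pair, (lo, hi) in constraints.gaps.items():
        a, b = pair.split("-")
        ok &= lo <= r[b].span[0] - r[a].span[1] <= hi
    amp = r["B3"].span[1] - r["F3"].span[0]
    ok &= constraints.amplicon_span[0] <= amp <= constraints.amplicon_span[1]
    return bool(ok)


@pytest.fixture(scope="module")
def invariant_pair(
):
    rng = np.random.default_rng(7)
    base = "".join("ACGT"[i] for i in rng.integers(4, size=300))
    target = _aln([base] * 5)
    nts = []
    for _ in range(10):
        s = list(base)
        for site in rng.choice(300, size=45, replace=False):  # ~15% divergent
            s[site] = "ACGT"[rng.integers(4)]
        nts.append("".join(s))
    return target, _aln(nts, role="non-target")


class TestEnumerate:
    def test_invariant_alignment_yields_candidates(self, invariant_pair):
        target, nontarget = invariant_pair
        constraints = GeometryConstraints()
        res = enumerate_candidates(target, nontarget, constraints,
                                   SearchLimits(max_candidates=100))
        assert len(res) >= 1
        for c in res:
            assert validate_candidate_geometry(c, constraints)
            assert _naive_geometry_check(c, constraints)

    def test_alignment_shorter_than_amplicon_is_empty_with_diagnostics(self):
        target = _aln(["ACGTACGT" * 10])  # 80 columns < 120 minimum span
        nontarget = _aln(["ACGTACGT" * 10], role="non-target")
        res = enumerate_candidates(target, nontarget)
        assert len(res) == 0
        assert res.diagnostics["candidates"] == 0
        assert any(k.startswith("feasible_spans") or k.startswith("amplicon")
                   for k in res.diagnostics)

    def test_hypervariable_block_excluded_by_degeneracy_cap(self, rng):
        base = list("".join("ACGT"[i] for i in rng.integers(4, size=360)))
        seqs = []
        for i in range(4):
            s = base.copy()
            for j in range(150, 200):  # 50-column hypervariable block
                s[j] = "ACGT"[(i + j) % 4]
            seqs.append("".join(s))
        target = _aln(seqs)
        nontarget = _aln(["".join(base)], role="non-target")
        res = enumerate_candidates(target, nontarget,
                                   limits=SearchLimits(max_candidates=200))
        block = range(150, 200)
        for c in res:
            for region in c.regions.values():
                s, e = region.span
                # any >=18-mer inside the block has degeneracy 4**18 >> 16
                assert not (s >= block.start and e <= block.stop)

    def test_determinism(self, invariant_pair):
        target, nontarget = invariant_pair
        a = enumerate_candidates(target, nontarget, limits=SearchLimits(max_candidates=50))
        b = enumerate_candidates(target, nontarget, limits=SearchLimits(max_candidates=50))
        assert [tuple(sorted((n, r.span) for n, r in c.regions.items())) for c in a] == \
               [tuple(sorted((n, r.span) for n, r in c.regions.items())) for c in b]


class TestApplyDegeneracy:
    def test_invariant_target_keeps_sequences(self, invariant_pair):
        target, nontarget = invariant_pair
        res = enumerate_candidates(target, nontarget, limits=SearchLimits(max_candidates=5))
        c = apply_degeneracy(res.candidates[0], target)
        assert all(p.degeneracy == 1 for p in c.primer_set.primers().values())

    def test_planted_rry_gives_bip_degeneracy_8(self, design_fixture):
        res = enumerate_candidates(design_fixture.target, design_fixture.nontarget)
        assert len(res) == 1
        c = apply_degeneracy(res.candidates[0], design_fixture.target)
        assert c.primer_set.bip.degeneracy == 8
        assert c.primer_set.fip.degeneracy == 1
        codes = set(c.primer_set.bip.sequence) - set("ACGT")
        assert codes == {"R", "Y"}

    def test_consensus_equals_columnwise_union(self, design_fixture):
        target = design_fixture.target
        profiles = column_profiles(target)
        res = enumerate_candidates(target, design_fixture.nontarget)
        c = apply_degeneracy(res.candidates[0], target)
        for region in c.regions.values():
            s, e = region.span
            plus = "".join(p.consensus_code for p in profiles[s:e])
            if region.strand == "plus":
                assert region.sequence == plus
            else:
                from lampsmith.iupac import reverse_complement
                assert region.sequence == reverse_complement(plus)


class TestScoring:
    def test_rank_equals_weighted_sum_recomputation(self, design_fixture):
        res = search(design_fixture.target, design_fixture.nontarget, top=1)
        c = res.candidates[0]
        w = ScoreWeights()
        comp = c.score_components
        expected = (w.degeneracy * comp["neg_log2_degeneracy"]
                    + w.exclusivity * comp["min_nontarget_mismatches"]
                    - w.self_structure * comp["self_structure_penalty"]
                    - w.tm_spread * comp["tm_spread"])
        assert c.rank_score == pytest.approx(expected, abs=1e-12)

    def test_lower_degeneracy_ranks_higher_all_else_equal(self):
        planted = synth.make_design_fixture(seed=3, plant_polymorphisms=True)
        plain = synth.make_design_fixture(seed=3, plant_polymorphisms=False)
        c_planted = search(planted.target, planted.nontarget, top=1).candidates[0]
        c_plain = search(plain.target, plain.nontarget, top=1).candidates[0]
        # identical consensus and layout; only the planted polymorphism differs
        assert c_plain.primer_set.bip.degeneracy == 1
        assert c_planted.primer_set.bip.degeneracy == 8
        assert c_plain.rank_score > c_planted.rank_score

    def test_more_nontarget_mismatches_rank_higher(self, design_fixture):
        target = design_fixture.target
        profiles = column_profiles(target)
        res = enumerate_candidates(target, design_fixture.nontarget)
        cand = apply_degeneracy(res.candidates[0], target)

        near = _aln([target.sequences[0]], role="non-target")  # 0 mismatches
        far = design_fixture.nontarget  # ~10% divergent
        cache = {}
        r_near = score_candidate(apply_degeneracy(res.candidates[0], target),
                                 NonTargetIndex(target, near, profiles=profiles),
                                 _tm_cache=cache).rank_score
        r_far = score_candidate(cand,
                                NonTargetIndex(target, far, profiles=profiles),
                                _tm_cache=cache).rank_score
        assert r_far >= r_near

    def test_exclusivity_bonus_saturates_above_three(self, design_fixture):
        res = search(design_fixture.target, design_fixture.nontarget, top=1)
        assert res.candidates[0].score_components["min_nontarget_mismatches"] <= 4


class TestSearch:
    def test_unique_layout_is_found_and_ranked_first(self, design_fixture):
        res = search(design_fixture.target, design_fixture.nontarget, top=10)
        assert len(res.candidates) == 1
        spans = {n: r.span for n, r in res.candidates[0].regions.items()}
        assert spans == design_fixture.expected_spans

    def test_search_is_deterministic(self, design_fixture):
        a = search(design_fixture.target, design_fixture.nontarget, top=5)
        b = search(design_fixture.target, design_fixture.nontarget, top=5)
        assert [c.rank_score for c in a] == [c.rank_score for c in b]

    def test_loops_preferred_at_equal_scores(self, invariant_pair):
        target, nontarget = invariant_pair
        res = search(target, nontarget, limits=SearchLimits(max_candidates=40), top=40)
        by_rank = {}
        for c in res.candidates:
            by_rank.setdefault(round(c.rank_score, 9), []).append(c.has_loops)
        for loops in by_rank.values():
            # within an exact rank tie, loop-bearing candidates come first
            assert loops == sorted(loops, reverse=True)


def test_constraint_validation():
    with pytest.raises(ValueError):
        GeometryConstraints(amplicon_span=(300, 120))
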