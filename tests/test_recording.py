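"""Blacklist construction, valid/wrong classification, percent mutation,
positional profiles and indel-score CDFs."""

import numpy as np
import pytest

from clonescribe import (
    StgTriplet,
    align_score,
    build_blacklist,
    classify_stg,
    percent_mutation,
    position_profile,
    score_cdf,
    score_triplets,
)

from .conftest import substitute


def variant_with_score(template: str, target: float) -> str:
    """Construct a variant with a known mutation score from the template."""
    if target == 3.5:  # one mismatch + one-base deletion
        v = substitute(template, 2, "A" if template[2] != "A" else "C")
        return v[:10] + v[11:]
    if target == 4.0:  # four-base deletion: 2.5 + 3 * 0.5
        return template[:8] + template[12:]
    if target == 4.5:  # two mismatches + one-base deletion
        v = substitute(template, 1, "A" if template[1] != "A" else "C")
        v = substitute(v, 4, "A" if template[4] != "A" else "C")
        return v[:10] + v[11:]
    raise ValueError(target)


class TestBlacklist:
    def test_pure_template_plasmid_gives_empty_blacklist(self, template):
        assert build_blacklist({template: 1000}, template) == set()

    def test_threshold_is_inclusive_at_4(self, template):
        v35 = variant_with_score(template, 3.5)
        v40 = variant_with_score(template, 4.0)
        v45 = variant_with_score(template, 4.5)
        assert align_score(v35, template).total == pytest.approx(3.5)
        assert align_score(v40, template).total == pytest.approx(4.0)
        assert align_score(v45, template).total == pytest.approx(4.5)
        blk = build_blacklist({template: 900, v35: 40, v40: 30, v45: 30}, template)
        assert blk == {v40, v45}

    def test_planted_wrong_templates_recovered_exactly(self, template, rng):
        bases = np.array(list("ACGT"))
        planted = set()
        while len(planted) < 5:
            w = "".join(rng.choice(bases, 20))
            if align_score(w, template).total >= 4.0:
                planted.add(w)
        counts = {template: 10000, **{w: 5 for w in planted}}
        assert build_blacklist(counts, template) == planted


class TestClassify:
    def test_template_is_valid(self, template):
        blk = {variant_with_score(template, 4.5)}
        assert classify_stg(template, template, blk) == "valid"

    def test_blacklist_member_is_wrong(self, template):
        member = variant_with_score(template, 4.5)
        assert classify_stg(member, template, {member}) == "wrong"

    def test_equidistant_variant_retained_as_valid(self, template):
        # one mismatch from the template, and the member differs from the
        # template by a different single mismatch: scores tie at 1.0 each way?
        # build explicit tie: variant at distance d from both
        member = substitute(template, 3, "A" if template[3] != "A" else "C")
        variant = substitute(template, 9, "A" if template[9] != "A" else "C")
        d_t = align_score(variant, template).total
        d_m = align_score(variant, member).total
        assert d_t < d_m  # sanity: closer to template -> valid
        assert classify_stg(variant, template, {member}) == "valid"
        # exact tie: a third base at the member's mutated position is one
        # mismatch from the template and one from the member
        third = next(b for b in "ACGT" if b not in (template[3], member[3]))
        halfway = substitute(template, 3, third)
        assert align_score(halfway, template).total == align_score(halfway, member).total
        assert classify_stg(halfway, template, {member}) == "valid"

    def test_near_member_read_is_wrong(self, template):
        member = variant_with_score(template, 4.5)
        near = substitute(member, 0, "A" if member[0] != "A" else "C")
        assert align_score(near, member).total < align_score(near, template).total
        assert classify_stg(near, template, {member}) == "wrong"


class TestPercentMutation:
    def test_unedited_sample_is_zero(self, template):
        trips = [StgTriplet("A" * 30, template, 50)]
        assert percent_mutation(trips, template) == 0.0

    def test_fully_edited_sample_is_hundred(self, template):
        edited = template[:10] + template[12:]
        trips = [StgTriplet("A" * 30, edited, 7)]
        assert percent_mutation(trips, template) == 100.0

    def test_read_weighting(self, template):
        edited = template[:10] + template[12:]
        trips = [
            StgTriplet("A" * 30, template, 75),
            StgTriplet("A" * 30, edited, 25),
        ]
        assert percent_mutation(trips, template) == pytest.approx(25.0)

    def test_mismatches_do_not_count_as_mutation(self, template):
        noisy = substitute(template, 4, "A" if template[4] != "A" else "C")
        trips = [StgTriplet("A" * 30, noisy, 10)]
        assert percent_mutation(trips, template) == 0.0

    def test_per_barcode_weighting(self, template):
        edited = template[:10] + template[12:]
        trips = [
            StgTriplet("A" * 30, edited, 90),   # clone fully mutated
            StgTriplet("C" * 30, template, 10),  # clone unmutated
        ]
        assert percent_mutation(trips, template) == pytest.approx(90.0)
        assert percent_mutation(trips, template, per_barcode=True) == pytest.approx(50.0)

    def test_no_valid_reads_raises(self, template):
        with pytest.raises(ValueError):
            percent_mutation([], template)


class TestPositionProfile:
    def test_unedited_profile_is_all_zero(self, template):
        prof = position_profile([StgTriplet("A" * 30, template, 5)], template)
        assert (prof.to_numpy() == 0).all()
        assert list(prof.index) == list(range(1, 21))

    def test_single_alignment_rates_equal_its_path(self, template):
        q = substitute(template, 6, "A" if template[6] != "A" else "C")
        q = q[:12] + q[13:]  # deletion of template position 13
        prof = position_profile([StgTriplet("A" * 30, q, 3)], template)
        assert prof.loc[7, "mismatch"] == 1.0
        assert prof["deletion"].sum() == 1.0
        assert prof.loc[13, "deletion"] == 1.0
        assert prof["insertion"].sum() == 0.0

    def test_insertion_assigned_to_following_position(self, template):
        q = template[:15] + "G" + template[15:]
        path = align_score(q, template)
        prof = position_profile([StgTriplet("A" * 30, q, 1)], template)
        assert prof["insertion"].sum() == 1.0
        # the single insertion sits before one template position
        assert (prof["insertion"] == 1.0).sum() == 1

    def test_wrong_reads_excluded(self, template):
        member = template[:8] + template[12:]  # score 4.0 -> blacklistable
        blk = build_blacklist({template: 100, member: 5}, template)
        trips = [StgTriplet("A" * 30, template, 10), StgTriplet("A" * 30, member, 10)]
        prof = position_profile(trips, template, blacklist=blk)
        assert (prof.to_numpy() == 0).all()


class TestScoreCdf:
    def test_all_zero_scores_single_step(self, template):
        cdf = score_cdf([StgTriplet("A" * 30, template, 9)], template)
        assert list(cdf["indel_score"]) == [0.0]
        assert list(cdf["cum_fraction"]) == [1.0]

    def test_two_equal_weight_scores(self, template):
        edited = template[:10] + template[11:]
        trips = [StgTriplet("A" * 30, template, 5), StgTriplet("A" * 30, edited, 5)]
        cdf = score_cdf(trips, template)
        assert list(cdf["indel_score"]) == [0.0, 2.5]
        assert list(cdf["cum_fraction"]) == pytest.approx([0.5, 1.0])

    def test_read_weighted_ecdf_matches_direct_computation(self, template):
        e1 = template[:10] + template[11:]       # 2.5
        e2 = template[:10] + template[13:]       # 3.5
        trips = [
            StgTriplet("A" * 30, template, 2),
            StgTriplet("C" * 30, e1, 5),
            StgTriplet("G" * 30, e2, 3),
        ]
        cdf = score_cdf(trips, template)
        assert list(cdf["indel_score"]) == [0.0, 2.5, 3.5]
        assert list(cdf["cum_fraction"]) == pytest.approx([0.2, 0.7, 1.0])


def test_score_triplets_frame_is_consistent(template):
    edited = template[:10] + template[11:]
    df = score_triplets(
        [StgTriplet("A" * 30, template, 3), StgTriplet("A" * 30, edited, 2)],
        template,
    )
    assert list(df["total"]) == pytest.approx([0.0, 2.5])
    assert (df["total"] == df["mismatch"] + df["insertion"] + df["deletion"]).all()
    assert set(df["status"]) == {"valid"}
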