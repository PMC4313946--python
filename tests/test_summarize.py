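"""The nine summarization systems and their contracts."""

import math
import random
from collections import Counter

import pytest

from figsummary import (
    CentroidParams,
    GoldStandard,
    baseline_centroid_full,
    baseline_figsum,
    baseline_random_para,
    baseline_random_sent,
    build_tfidf_index,
    centroid_scores,
    default_n,
    parse_plaintext_article,
    summarize,
    summarize_hybrid,
    summarize_paragraph,
    summarize_similarity,
    summarize_surface_cue,
    summarize_tfidf,
)
from figsummary.summarize import SCORE_TOL, top_n_by_score
from figsummary.synthetic import SynthParams, generate_article


def _article(paragraphs, captions=("alpha beta caption",)):
    parts = ["Title line", ""]
    for p in paragraphs:
        parts += [p, ""]
    for i, c in enumerate(captions, start=1):
        parts += [f"FIGURE {i}: {c}", ""]
    return parse_plaintext_article("\n".join(parts), article_id="t")


class TestTopN:
    def test_brute_force_oracle_with_ties(self):
        """Quantized-sort selection equals a sort-then-prefix oracle on 200
        random score vectors with deliberate ties."""
        rng = random.Random(7)
        for _ in range(200):
            size = rng.randrange(1, 30)
            pool = [rng.choice([0.0, 0.25, 0.5, rng.random()]) for _ in range(size)]
            scores = {i: pool[i] for i in range(size)}
            n = rng.randrange(1, size + 1)
            oracle = sorted(scores, key=lambda i: (-scores[i], i))[:n]
            assert [sid for sid, _ in top_n_by_score(scores, n)] == oracle

    def test_tolerance_treats_near_ties_as_ties(self):
        scores = {0: 0.5, 1: 0.5 + SCORE_TOL / 4}
        assert [sid for sid, _ in top_n_by_score(scores, 1)] == [0]


class TestSimilarityAndTfidf:
    @pytest.mark.parametrize("fn", [summarize_similarity, summarize_tfidf])
    def test_unique_maximizer(self, fn):
        art = _article([
            "Alpha beta gamma appear together.",
            "Unrelated words entirely different.",
            "Another unrelated sentence here.",
        ])
        out = fn(art, art.figure(1), 1)
        assert out.document_order_ids == [0]

    @pytest.mark.parametrize("fn", [summarize_similarity, summarize_tfidf])
    def test_all_zero_ties_pick_document_order(self, fn):
        art = _article([
            "Unrelated one here now.", "Unrelated two here now.",
            "Unrelated three here now.",
        ], captions=("totally disjoint caption words",))
        out = fn(art, art.figure(1), 2)
        assert out.document_order_ids == [0, 1]

    @pytest.mark.parametrize("fn", [summarize_similarity, summarize_tfidf])
    def test_n_capped_by_candidates(self, fn):
        art = _article(["Alpha beta here.", "Gamma delta there."])
        assert len(fn(art, art.figure(1), 99)) == 2

    def test_empty_caption_is_error(self):
        art = _article(["Some sentence here."])
        empty = type(art.figures[0])(
            figure_number=1, label="Figure 1", caption="", caption_missing=True
        )
        with pytest.raises(ValueError, match="empty caption"):
            summarize_similarity(art, empty, 1)


class TestSurfaceCueAndParagraph:
    def test_extracts_exactly_referring_sentences(self):
        art = _article([
            "Intro sentence without cues. Another plain one.",
            "Levels rose (Fig. 1). A neighbour sentence.",
            "Final paragraph mentions Fig. 1 again. Plus filler.",
        ])
        out = summarize_surface_cue(art, art.figure(1))
        assert out.document_order_ids == [2, 4]

    def test_empty_when_no_references(self):
        art = _article(["No cues anywhere here."])
        assert len(summarize_surface_cue(art, art.figure(1))) == 0
        assert len(summarize_paragraph(art, art.figure(1))) == 0

    def test_multi_figure_range_lands_in_all_summaries(self):
        art = _article(
            ["Results shown in Figs. 1–3 were consistent. Filler sentence here."],
            captions=("c one", "c two", "c three"),
        )
        for fignum in (1, 2, 3):
            out = summarize_surface_cue(art, art.figure(fignum))
            assert 0 in out.sentence_ids

    def test_paragraph_extracts_whole_paragraphs(self):
        art = _article([
            "First alpha. Second beta. Third with Fig. 1 cue. Fourth delta.",
            "Separate paragraph without cues.",
        ])
        out = summarize_paragraph(art, art.figure(1))
        assert out.document_order_ids == [0, 1, 2, 3]

    def test_two_referring_paragraphs_no_duplicates(self):
        art = _article([
            "Cue here (Fig. 1). Same paragraph mate.",
            "Middle paragraph plain.",
            "Another cue (Fig. 1) later. Its neighbour.",
        ])
        out = summarize_paragraph(art, art.figure(1))
        assert out.document_order_ids == [0, 1, 3, 4]

    def test_surface_cue_subset_of_paragraph(self, synth_article):
        art = synth_article.article
        for f in art.figures:
            assert (
                summarize_surface_cue(art, f).sentence_ids
                <= summarize_paragraph(art, f).sentence_ids
            )


class TestCentroid:
    def test_single_candidate_is_maximal(self):
        art = _article(["Only sentence here now."])
        scores = centroid_scores([0], art)
        assert set(scores) == {0}

    def test_identical_sentences_share_centroid_component(self):
        art = _article(["Alpha beta gamma delta.", "Alpha beta gamma delta."])
        params = CentroidParams(weight_position=0.0, weight_first_overlap=0.0)
        scores = centroid_scores([0, 1], art, params=params)
        assert scores[0] == pytest.approx(scores[1])

    def test_hand_computed_centroid_winner(self):
        # sentences: {alpha beta}, {alpha}, {beta gamma}; centroid_size=1,
        # weights (1,0,0).  idf: alpha,beta ln(4/3); gamma ln(2).
        # mean weights: alpha=beta=2*ln(4/3)/3 ~ 0.192, gamma=ln(2)/3 ~ 0.231
        # -> centroid {gamma}; only sentence 2 contains it.
        art = _article(["Alpha beta.", "Alpha.", "Beta gamma."])
        params = CentroidParams(
            centroid_size=1, weight_centroid=1.0, weight_position=0.0,
            weight_first_overlap=0.0,
        )
        scores = centroid_scores([0, 1, 2], art, params=params)
        expected_gamma_mean = math.log(2) / 3
        assert scores[2] == pytest.approx(expected_gamma_mean)
        assert scores[0] == scores[1] == 0.0

    def test_position_component(self):
        art = _article(["One sentence alpha.", "Two sentence beta.", "Three sentence gamma."])
        params = CentroidParams(weight_centroid=0.0, weight_first_overlap=0.0)
        scores = centroid_scores([0, 1, 2], art, params=params)
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(2 / 3)
        assert scores[2] == pytest.approx(1 / 3)

    def test_empty_candidates_is_error(self):
        art = _article(["A sentence here."])
        with pytest.raises(ValueError, match="empty"):
            centroid_scores([], art)


class TestHybrid:
    def test_subset_of_paragraph_and_cap(self, synth_article):
        art = synth_article.article
        for f in art.figures:
            para_ids = summarize_paragraph(art, f).sentence_ids
            hy = summarize_hybrid(art, f, 2)
            assert hy.sentence_ids <= para_ids
            hy_all = summarize_hybrid(art, f, 10_000)
            assert hy_all.sentence_ids == para_ids

    def test_empty_without_referring_paragraphs(self):
        art = _article(["No cues in this text at all."])
        assert len(summarize_hybrid(art, art.figure(1), 3)) == 0


class TestRandomBaselines:
    def test_determinism_and_full_draw(self, synth_article):
        art = synth_article.article
        f = art.figures[0]
        a = baseline_random_sent(art, f, 5, seed=123)
        b = baseline_random_sent(art, f, 5, seed=123)
        assert a.selected == b.selected
        assert baseline_random_sent(art, f, len(art), seed=1).sentence_ids == set(
            range(len(art))
        )

    def test_uniform_frequency(self):
        """Each sentence drawn with frequency 1/N within 3 sigma over 10,000 draws."""
        art = _article(["%s sentence filler here." % w for w in
                        ("One", "Two", "Three", "Four", "Five",
                         "Six", "Seven", "Eight", "Nine", "Ten")])
        n_draws, N = 10_000, len(art)
        counts = Counter()
        for s in range(n_draws):
            picked = baseline_random_sent(art, art.figures[0], 1, seed=s)
            counts.update(picked.sentence_ids)
        p = 1 / N
        sigma = math.sqrt(p * (1 - p) / n_draws)
        for sid in range(N):
            assert abs(counts[sid] / n_draws - p) <= 3 * sigma

    def test_random_para_picks_paragraph_initial(self, synth_article):
        art = synth_article.article
        starts = {rng.start for _, rng in art.paragraphs}
        out = baseline_random_para(art, art.figures[0], 3, seed=9)
        assert out.sentence_ids <= starts
        assert len(out) == 3

    def test_random_para_single_paragraph(self):
        art = _article(["Only one paragraph. With two sentences."])
        out = baseline_random_para(art, art.figures[0], 5, seed=0)
        assert out.document_order_ids == [0]


class TestCentroidFullAndFigsum:
    def test_figure_independent(self):
        art = _article(
            ["Alpha beta gamma here.", "Delta epsilon zeta there."],
            captions=("c one", "c two"),
        )
        s1 = baseline_centroid_full(art, art.figure(1), 1)
        s2 = baseline_centroid_full(art, art.figure(2), 1)
        assert s1.sentence_ids == s2.sentence_ids

    def test_single_sentence_article(self):
        art = _article(["Lone sentence stands."])
        assert baseline_centroid_full(art, art.figure(1), 3).document_order_ids == [0]

    def test_one_pick_per_category(self, headed_article):
        from figsummary.summarize import _imrad_category

        out = baseline_figsum(headed_article, headed_article.figure(1))
        assert 1 <= len(out) <= 4
        cats = [
            _imrad_category(headed_article.sentences[i].section_label)
            for i in out.document_order_ids
        ]
        assert len(cats) == len(set(cats))

    def test_category_winner_is_argmax(self):
        """Recompute the two-part score by hand on a six-sentence fixture."""
        text = ("Central theme title\n\n"
                "# Methods\nCaption words alpha beta occur here. "
                "Nothing shared at all.\n\n"
                "# Results\nAlpha beta appear again together. Plain filler words only. "
                "Central theme title words. Last filler sentence closes.\n\n"
                "FIGURE 1: alpha beta caption words.\n")
        art = parse_plaintext_article(text, article_id="h")
        from figsummary import cosine_similarity, tfidf_vector, tokenize
        from figsummary.summarize import _imrad_category

        idx = build_tfidf_index(art)
        cap = tfidf_vector(tokenize(art.figures[0].caption), idx)
        theme = tfidf_vector(tokenize(art.title + " "), idx)
        by_cat: dict[str, tuple[float, int]] = {}
        for s in art.sentences:
            v = tfidf_vector(tokenize(s.text), idx)
            score = cosine_similarity(v, cap) + cosine_similarity(v, theme)
            cat = _imrad_category(s.section_label)
            if cat not in by_cat or score > by_cat[cat][0]:
                by_cat[cat] = (score, s.sentence_id)
        out = baseline_figsum(art, art.figures[0])
        assert out.sentence_ids == {sid for _, sid in by_cat.values()}


class TestDefaultN:
    @pytest.mark.parametrize("micro,expected", [(7.21, 8), (10.34, 11), (5.0, 5)])
    def test_ceiling(self, micro, expected):
        assert default_n(micro) == expected

    def test_from_gold(self):
        gold = GoldStandard(entries={("a", 1): {0, 1, 2}, ("a", 2): {3, 4}})
        assert default_n(gold) == 3  # micro = 5/2 -> ceil 3

    def test_empty_gold_is_error(self):
        with pytest.raises(ValueError):
            default_n(GoldStandard())


class TestDispatch:
    def test_unknown_system_lists_valid_names(self, synth_article):
        art = synth_article.article
        with pytest.raises(ValueError, match="similarity"):
            summarize("nope", art, art.figures[0])

    def test_random_requires_seed(self, synth_article):
        art = synth_article.article
        with pytest.raises(ValueError, match="seed"):
            summarize("random_sent", art, art.figures[0], n=3)

    @pytest.mark.parametrize("name", ["similarity", "tfidf", "hybrid"])
    def test_ranked_systems_require_n(self, name, synth_article):
        art = synth_article.article
        with pytest.raises(ValueError, match="n >= 1"):
            summarize(name, art, art.figures[0])
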