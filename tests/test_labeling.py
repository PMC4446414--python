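import numpy as np
import pytest

from seqtu.annotation_io import Gene, GenomeAnnotation, derive_gene_pairs
from seqtu.coverage import Reads
from seqtu.features import continuity_features
from seqtu.labeling import (
    CTU,
    LabeledPair,
    LengthDensity,
    construct_ctus,
    expression_ratio,
    fit_length_densities,
    select_negative_pairs,
    select_positive_pairs_by_spanning,
)

from conftest import make_track


def two_gene_annotation(ir=(100, 160), length=260, strand="+"):
    return GenomeAnnotation(
        genome_id="chr",
        length=length,
        genes=(
            Gene(id="L", strand=strand, start=0, end=ir[0]),
            Gene(id="R", strand=strand, start=ir[1], end=length),
        ),
    )


def track_from_means(ann, left_mean, ir_values, right_mean):
    (pair,) = derive_gene_pairs(ann)
    plus = np.zeros(ann.length, dtype=int)
    plus[pair.left.start : pair.left.end] = left_mean
    plus[pair.intergenic.start : pair.intergenic.end] = ir_values
    plus[pair.right.start : pair.right.end] = right_mean
    return make_track(ann.length, plus=plus), pair


def test_negative_selection_requires_both_criteria():
    ann = two_gene_annotation()
    ir = np.zeros(60, dtype=int)
    ir[:24] = 5  # gap fraction 0.6
    # ratio (201)/(15+1) > 10 and gap 0.6 -> negative
    track, pair = track_from_means(ann, 200, ir, 15)
    assert len(select_negative_pairs([pair], track)) == 1
    # same gap but ratio ~ 5 -> rejected (conjunction)
    track2, pair2 = track_from_means(ann, 75, ir, 15)
    assert select_negative_pairs([pair2], track2) == []
    # gap exactly 0.5 with huge ratio -> rejected (strict >)
    ir_half = np.zeros(60, dtype=int)
    ir_half[:30] = 5
    track3, pair3 = track_from_means(ann, 500, ir_half, 2)
    _, gap = continuity_features(track3, (100, 160), "+")
    assert gap == 0.5
    assert select_negative_pairs([pair3], track3) == []


def test_positive_selection_by_spanning_evidence():
    ann = two_gene_annotation()
    track, pair = track_from_means(ann, 30, np.full(60, 20), 20)
    spanning = Reads([90], [200], [True])
    assert len(select_positive_pairs_by_spanning([pair], spanning, track)) == 1
    # partial cover of the intergenic region does not qualify
    partial = Reads([110], [200], [True])
    assert select_positive_pairs_by_spanning([pair], partial, track) == []
    # evidence on the wrong strand does not qualify when stranded
    wrong = Reads([90], [200], [False])
    assert select_positive_pairs_by_spanning([pair], wrong, track) == []
    assert len(select_positive_pairs_by_spanning([pair], wrong, track, stranded=False)) == 1


def test_positive_selection_ratio_boundary_is_inclusive():
    ann = two_gene_annotation()
    # mean ratio exactly 2.0 with pseudocount: (39+1)/(19+1) = 2
    track, pair = track_from_means(ann, 39, np.full(60, 20), 19)
    assert expression_ratio(track, (0, 100), (160, 260), "+") == pytest.approx(2.0)
    spanning = Reads([90], [200], [True])
    assert len(select_positive_pairs_by_spanning([pair], spanning, track)) == 1
    # just above two-fold -> rejected
    track2, pair2 = track_from_means(ann, 45, np.full(60, 20), 19)
    assert select_positive_pairs_by_spanning([pair2], spanning, track2) == []


def test_labeled_sets_are_disjoint_by_construction(default_sim, default_run):
    keys = {"negative": set(), "positive": set()}
    for lp in default_run.labeled:
        if isinstance(lp.pair, CTU):
            continue
        keys[lp.label].add(lp.pair.key)
    assert not keys["negative"] & keys["positive"]


def test_label_source_consistency_enforced():
    with pytest.raises(ValueError, match="inconsistent"):
        LabeledPair(pair=None, label="positive", source="gap_filter")


def test_length_density_ratio_arithmetic():
    ann = GenomeAnnotation(
        genome_id="chr",
        length=2000,
        genes=(
            Gene(id="a", strand="+", start=0, end=400),
            Gene(id="b", strand="+", start=500, end=1000),
            Gene(id="c", strand="+", start=1100, end=1500),
            Gene(id="d", strand="-", start=1600, end=1700),
            Gene(id="e", strand="-", start=1750, end=1850),
            Gene(id="f", strand="-", start=1900, end=1990),
        ),
    )
    densities = fit_length_densities(ann)
    ir_density, gd_density = densities["+"]
    # first pair: |ir|=100, |g1|=400, |g2|=500 -> both ratios 0.1
    assert ir_density.observations[0] == pytest.approx(0.1)
    assert gd_density.observations[0] == pytest.approx(0.1)
    assert ir_density.kind == "IR" and gd_density.kind == "GD"


def test_length_density_requires_two_eligible_pairs():
    ann = GenomeAnnotation(
        genome_id="chr",
        length=1000,
        genes=(
            Gene(id="a", strand="+", start=0, end=100),
            Gene(id="b", strand="+", start=200, end=300),
            Gene(id="c", strand="-", start=400, end=500),
            Gene(id="d", strand="-", start=600, end=700),
        ),
    )
    with pytest.raises(ValueError, match="insufficient pairs"):
        fit_length_densities(ann)


def test_density_sampling_is_seeded_and_unbiased():
    density = LengthDensity(np.array([0.05, 0.1, 0.2, 0.4]), "IR")
    draws1 = density.sample(np.random.default_rng(5), size=10_000)
    draws2 = density.sample(np.random.default_rng(5), size=10_000)
    assert np.array_equal(draws1, draws2)
    se = density.observations.std() / np.sqrt(len(draws1))
    assert abs(draws1.mean() - density.observations.mean()) < 3 * se


def _ctu_annotation(sequence):
    return GenomeAnnotation(
        genome_id="chr",
        length=len(sequence),
        genes=(Gene(id="target", strand="+", start=0, end=len(sequence)),),
        sequence=sequence,
    )


class FixedDensity:
    """Degenerate density returning one fixed ratio (placement tests)."""

    def __init__(self, value):
        self.value = value

    def sample(self, rng, size=None):
        return self.value if size is None else np.full(size, self.value)


def test_ctu_window_arithmetic():
    """|g|=1000, p=0.1, q=0.2: cIR length 100 searched over offsets [350, 450]."""
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("AT"), size=1000))
    seq = seq[:350] + "G" * 10 + seq[360:]  # GC-rich patch inside the window
    ann = _ctu_annotation(seq)
    track = make_track(1000, plus=np.full(1000, 10))
    densities = {"+": (FixedDensity(0.1), FixedDensity(0.2)), "-": (FixedDensity(0.1), FixedDensity(0.2))}
    (ctu,) = construct_ctus(ann, densities, track, seed=0, min_cir_length=50)
    assert ctu.cir_end - ctu.cir_start == 100
    assert 350 <= ctu.cir_start <= 450
    # the GC patch at 350..360 forces the window to start past it
    assert ctu.cir_start >= 360 or ctu.cir_start + 100 <= 350


def test_ctu_placement_on_obvious_at_run():
    """A pure-A run inside a G background is the unique GC minimum."""
    seq = "G" * 450 + "A" * 100 + "G" * 450
    ann = _ctu_annotation(seq)
    track = make_track(1000, plus=np.full(1000, 10))
    densities = {"+": (FixedDensity(0.1), FixedDensity(0.5)), "-": (FixedDensity(0.1), FixedDensity(0.5))}
    (ctu,) = construct_ctus(ann, densities, track, seed=0, min_cir_length=50)
    assert (ctu.cir_start, ctu.cir_end) == (450, 550)


def brute_force_min_gc_start(sequence, gene_start, gene_len, L, lo, hi):
    best_start, best_gc = None, None
    for j in range(lo, hi + 1):
        window = sequence[gene_start + j : gene_start + j + L]
        gc = sum(1 for b in window if b in "GC")
        if best_gc is None or gc < best_gc:
            best_gc, best_start = gc, j
    return best_start


def test_ctu_gc_placement_matches_exhaustive_scan_on_random_genes():
    rng = np.random.default_rng(99)
    for trial in range(60):
        glen = int(rng.integers(300, 1200))
        seq = "".join(rng.choice(list("ACGT"), size=glen))
        ann = _ctu_annotation(seq)
        track = make_track(glen, plus=np.full(glen, 5))
        p = float(rng.uniform(0.05, 0.4))
        q = float(rng.uniform(0.0, 0.5))
        densities = {"+": (FixedDensity(p), FixedDensity(q)), "-": (FixedDensity(p), FixedDensity(q))}
        ctus = construct_ctus(ann, densities, track, seed=0, min_cir_length=1)
        L = int(round(p * glen))
        if L < 1 or L > glen - 2:
            assert ctus == []
            continue
        (ctu,) = ctus
        m = glen / 2.0
        lo = min(max(int(round(m - L / 2.0 - q * glen / 2.0)), 1), glen - L - 1)
        hi = min(max(int(round(m - L / 2.0 + q * glen / 2.0)), 1), glen - L - 1)
        expected = brute_force_min_gc_start(seq, 0, glen, L, lo, hi)
        assert ctu.cir_start == expected, f"trial {trial}"


def test_emitted_ctus_satisfy_all_exclusion_filters(default_sim):
    from seqtu.labeling import fit_length_densities as fld

    ann = default_sim.truth.annotation
    track = default_sim.track
    densities = fld(ann)
    ctus = construct_ctus(ann, densities, track, seed=5)
    assert ctus, "default conditions should yield constructed TUs"
    for ctu in ctus:
        _, gap = continuity_features(track, (ctu.cir_start, ctu.cir_end), ctu.strand)
        assert gap <= 0.5
        assert expression_ratio(track, ctu.left_part, ctu.right_part, ctu.strand) <= 10.0
        assert ctu.cir_length >= 225
        # partition of the source gene
        gene = ann.gene_by_id(ctu.source_gene_id)
        assert ctu.left_part[0] == gene.start and ctu.right_part[1] == gene.end
        assert ctu.left_part[1] == ctu.cir_start and ctu.right_part[0] == ctu.cir_end
        assert ctu.left_part[1] > ctu.left_part[0] and ctu.right_part[1] > ctu.right_part[0]


def test_short_cir_draw_is_discarded():
    seq = "G" * 450 + "A" * 100 + "G" * 450
    ann = _ctu_annotation(seq)
    track = make_track(1000, plus=np.full(1000, 10))
    densities = {"+": (FixedDensity(0.1), FixedDensity(0.2)), "-": (FixedDensity(0.1), FixedDensity(0.2))}
    # L = 100 < 225 -> dropped by the length filter at defaults
    assert construct_ctus(ann, densities, track, seed=0) == []


def test_ctu_construction_is_seed_reproducible(default_sim):
    ann = default_sim.truth.annotation
    densities = fit_length_densities(ann)
    a = construct_ctus(ann, densities, default_sim.track, seed=123)
    b = construct_ctus(ann, densities, default_sim.track, seed=123)
    assert a == b
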