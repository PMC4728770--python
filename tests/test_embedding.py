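"""The coordinate→RGB transform, its floor, its inverse, its invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqcerosene import (
    MIN_SPAN_ANGSTROM,
    EmbeddingFrame,
    RepresentativeMode,
    compute_centroid,
    compute_spans,
    effective_s_max,
    embed_structure,
    point_to_rgb,
    rgb_to_point,
)
from seqcerosene.fixtures import make_collinear_chain, make_random_coil
from seqcerosene.structure_io import Chain, Structure

MODE = RepresentativeMode.C_BETA_DEFAULT

finite_coord = st.tuples(*(st.floats(-500, 500) for _ in range(3)))


def random_frame(rng) -> EmbeddingFrame:
    points = rng.uniform(-60, 60, size=(rng.integers(2, 40), 3))
    return EmbeddingFrame.from_points(points)


# --- centroid and spans -----------------------------------------------------

def test_centroid_examples():
    np.testing.assert_allclose(
        compute_centroid([(0, 0, 0), (2, 0, 0)]), [1.0, 0.0, 0.0]
    )
    np.testing.assert_allclose(compute_centroid([(1, 1, 1)]), [1.0, 1.0, 1.0])


def test_centroid_matches_explicit_summation():
    rng = np.random.default_rng(11)
    points = rng.normal(size=(5, 3))
    explicit = sum(points[i] for i in range(5)) / 5
    np.testing.assert_allclose(compute_centroid(points), explicit, atol=1e-12)


def test_centroid_empty_raises():
    with pytest.raises(ValueError):
        compute_centroid(np.empty((0, 3)))


def test_spans_symmetric_pair():
    assert compute_spans([(0, 0, 0), (10, 0, 0)], (5, 0, 0)) == (5.0, 0.0, 0.0, 5.0)


def test_spans_single_point_degenerate():
    assert compute_spans([(3, 4, 5)], (3, 4, 5)) == (0.0, 0.0, 0.0, 0.0)


def test_spans_match_brute_force_loop():
    rng = np.random.default_rng(3)
    points = rng.uniform(-20, 20, size=(6, 3))
    centroid = compute_centroid(points)
    expected = [max(abs(p[axis] - centroid[axis]) for p in points) for axis in range(3)]
    s_x, s_y, s_z, s_max = compute_spans(points, centroid)
    np.testing.assert_allclose([s_x, s_y, s_z], expected, atol=1e-12)
    assert s_max == max(expected)


@pytest.mark.parametrize(
    "raw, expected, floored",
    [(5.0, 23.0, True), (0.0, 23.0, True), (23.0, 23.0, False), (40.0, 40.0, False)],
)
def test_effective_s_max(raw, expected, floored):
    assert effective_s_max(raw) == (expected, floored)


def test_effective_s_max_rejects_negative():
    with pytest.raises(ValueError):
        effective_s_max(-1.0)


# --- forward transform ------------------------------------------------------

def _frame(centroid=(0, 0, 0), s=30.0) -> EmbeddingFrame:
    return EmbeddingFrame(np.asarray(centroid, float), (s, s, s), s, s, False)


def test_centroid_maps_to_mid_gray():
    frame = _frame((4.0, -2.0, 7.5))
    color = point_to_rgb(frame.centroid, frame)
    assert color.continuous == (128.0, 128.0, 128.0)
    assert color.integer == (128, 128, 128)


def test_extreme_points_hit_cube_faces():
    frame = _frame(s=30.0)
    hi = point_to_rgb((30.0, 0.0, 0.0), frame)
    lo = point_to_rgb((-30.0, 0.0, 0.0), frame)
    assert hi.c_red == 256.0 and hi.red == 255  # 256 clamps to the 8-bit max
    assert lo.c_red == 0.0 and lo.red == 0


def test_cube_side_is_256_channel_units():
    frame = _frame(s=45.0)
    plus = point_to_rgb((45.0, 0.0, 0.0), frame)
    minus = point_to_rgb((-45.0, 0.0, 0.0), frame)
    assert plus.c_red - minus.c_red == 256.0


def test_rounding_is_half_away_from_zero():
    frame = _frame(s=MIN_SPAN_ANGSTROM)
    # continuous 128.5 must round to 129, not bankers-round to 128
    offset = 0.5 * MIN_SPAN_ANGSTROM / 128.0
    assert point_to_rgb((offset, 0, 0), frame).red == 129


# --- inverse ----------------------------------------------------------------

def test_mid_gray_decodes_to_centroid():
    frame = _frame((1.5, 2.5, -3.0))
    np.testing.assert_allclose(
        rgb_to_point((128.0, 128.0, 128.0), frame), frame.centroid
    )


def test_channel_256_decodes_to_plus_span():
    frame = _frame((10.0, 0.0, 0.0), s=25.0)
    np.testing.assert_allclose(
        rgb_to_point((256.0, 128.0, 128.0), frame), [35.0, 0.0, 0.0]
    )


@settings(max_examples=300, deadline=None)
@given(seed=st.integers(0, 2**20), p=finite_coord)
def test_continuous_round_trip_exact(seed, p):
    """rgb_to_point(point_to_rgb(p)) recovers p to 1e-9 Å (bijectivity)."""
    frame = random_frame(np.random.default_rng(seed))
    color = point_to_rgb(np.array(p), frame)
    np.testing.assert_allclose(
        rgb_to_point(color.continuous, frame), p, atol=1e-9
    )


@settings(max_examples=200, deadline=None)
@given(seed=st.integers(0, 2**20))
def test_integer_round_trip_within_quantization_bound(seed):
    """8-bit channels recover in-structure coordinates to s_max/256 per axis."""
    rng = np.random.default_rng(seed)
    frame = random_frame(rng)
    s = frame.s_max_effective
    p = frame.centroid + rng.uniform(-1, 1, 3) * s
    color = point_to_rgb(p, frame)
    decoded = rgb_to_point(color.quantized, frame)
    assert np.all(np.abs(decoded - p) <= s / 256.0 + 1e-9)
    # the 8-bit display clamp affects only the attained cube face (256->255),
    # where the error is bounded by a full channel unit instead of half
    clamped = rgb_to_point(color.integer, frame)
    assert np.all(np.abs(clamped - p) <= s / 128.0 + 1e-9)


# --- whole-structure embedding ----------------------------------------------

def test_translated_chain_differs_only_in_red():
    base = make_random_coil(12, seed=5)
    shifted_chain = Chain("B")
    for residue in base.chains[0].residues:
        import copy

        twin = copy.deepcopy(residue)
        twin.chain_id = "B"
        for atom in twin.atoms:
            atom.coord = atom.coord + np.array([30.0, 0.0, 0.0])
        shifted_chain.residues.append(twin)
    both = Structure("pair", [base.chains[0], shifted_chain])
    embedding = embed_structure(both, MODE)
    colors = list(embedding.colors.values())
    n = len(base.chains[0].residues)
    for ca, cb in zip(colors[:n], colors[n:]):
        assert cb.c_red > ca.c_red
        assert cb.c_green == pytest.approx(ca.c_green, abs=1e-9)
        assert cb.c_blue == pytest.approx(ca.c_blue, abs=1e-9)


def test_coincident_points_all_mid_gray():
    structure = make_collinear_chain(1, 1.0)
    embedding = embed_structure(structure, MODE)
    assert embedding.frame.floor_applied
    assert embedding.frame.s_max_effective == MIN_SPAN_ANGSTROM
    (color,) = embedding.colors.values()
    assert color.integer == (128, 128, 128)


def test_far_compound_has_maximal_blue():
    from seqcerosene.structure_io import Atom, Residue, ResidueKind

    base = make_random_coil(10, seed=9, box=30.0)
    ligand = Residue("A", 500, "", "LIG", ResidueKind.HETERO,
                     [Atom("C1", "C", (0.0, 0.0, 80.0))], "LIG")
    base.compounds.append(ligand)
    embedding = embed_structure(base, MODE)
    blues = {ref: c.c_blue for ref, c in embedding.colors.items()}
    ligand_ref = next(r for r in blues if r.is_compound)
    assert blues[ligand_ref] == max(blues.values())


@settings(max_examples=100, deadline=None)
@given(seed=st.integers(0, 2**20), t=st.tuples(*(st.floats(-200, 200) for _ in range(3))))
def test_translation_invariance_of_colors(seed, t):
    """Rigid translation of all input coordinates changes no color."""
    a = make_random_coil(10, seed=seed)
    b = make_random_coil(10, seed=seed)
    for residue in b.polymer_residues():
        for atom in residue.atoms:
            atom.coord = atom.coord + np.array(t)
    ca = [c.continuous for c in embed_structure(a, MODE).colors.values()]
    cb = [c.continuous for c in embed_structure(b, MODE).colors.values()]
    np.testing.assert_allclose(cb, ca, atol=1e-7)


@settings(max_examples=100, deadline=None)
@given(seed=st.integers(0, 2**20), k=st.floats(1.0, 10.0))
def test_scale_invariance_above_floor(seed, k):
    """Scaling about the centroid leaves colors unchanged once span > 23 Å."""
    a = make_random_coil(10, seed=seed, box=80.0)
    emb_a = embed_structure(a, MODE)
    if emb_a.frame.s_max_raw <= MIN_SPAN_ANGSTROM:
        return
    center = emb_a.frame.centroid
    b = make_random_coil(10, seed=seed, box=80.0)
    for residue in b.polymer_residues():
        for atom in residue.atoms:
            atom.coord = center + k * (atom.coord - center)
    emb_b = embed_structure(b, MODE)
    np.testing.assert_allclose(
        [c.continuous for c in emb_b.colors.values()],
        [c.continuous for c in emb_a.colors.values()],
        atol=1e-7,
    )


@settings(max_examples=100, deadline=None)
@given(seed=st.integers(0, 2**20))
def test_channels_monotone_in_coordinates(seed):
    """Red strictly increases with x at fixed frame; likewise green/y, blue/z."""
    rng = np.random.default_rng(seed)
    frame = random_frame(rng)
    base = frame.centroid + rng.uniform(-20, 20, 3)
    for axis, channel in enumerate(["c_red", "c_green", "c_blue"]):
        step = np.zeros(3)
        step[axis] = rng.uniform(0.01, 10.0)
        lo = getattr(point_to_rgb(base, frame), channel)
        hi = getattr(point_to_rgb(base + step, frame), channel)
        assert hi > lo


@settings(max_examples=100, deadline=None)
@given(seed=st.integers(0, 2**20))
def test_in_structure_channels_within_color_cube(seed):
    """All structure points land in [0,256]; without the floor the cube
    boundary is attained on some channel."""
    structure = make_random_coil(15, seed=seed, box=70.0)
    embedding = embed_structure(structure, MODE)
    channels = np.array([c.continuous for c in embedding.colors.values()])
    assert channels.min() >= -1e-9 and channels.max() <= 256.0 + 1e-9
    if not embedding.frame.floor_applied:
        extremes = np.minimum(np.abs(channels - 0.0), np.abs(channels - 256.0))
        assert extremes.min() <= 1e-6
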