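"""Texture synthesis: glider geometry, statistic measurement, calibration,
and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gliderpsych.textures import (GliderKind, Texture, TextureParseError,
                                  TextureSpec, generate_texture,
                                  glider_offsets, measure_statistic,
                                  read_texture, statistic_profile,
                                  write_texture)

ALL_KINDS = list(GliderKind)
EVEN_KINDS = [GliderKind.BETA_H, GliderKind.BETA_V, GliderKind.BETA_DMAIN,
              GliderKind.BETA_DANTI, GliderKind.ALPHA]
ODD_KINDS = [k for k in ALL_KINDS if k not in EVEN_KINDS]


@pytest.mark.parametrize("kind, expected", [
    (GliderKind.GAMMA, [(0, 0)]),
    (GliderKind.BETA_H, [(0, 0), (0, 1)]),
    (GliderKind.BETA_V, [(0, 0), (1, 0)]),
    (GliderKind.BETA_DMAIN, [(0, 0), (1, 1)]),
    (GliderKind.BETA_DANTI, [(0, 1), (1, 0)]),
    (GliderKind.THETA_TL, [(0, 1), (1, 0), (1, 1)]),
    (GliderKind.THETA_BR, [(0, 0), (0, 1), (1, 0)]),
    (GliderKind.ALPHA, [(0, 0), (0, 1), (1, 0), (1, 1)]),
])
def test_glider_offsets(kind, expected):
    assert glider_offsets(kind) == expected


def test_glider_offsets_invariants():
    for kind in ALL_KINDS:
        offs = glider_offsets(kind)
        assert len(set(offs)) == len(offs) == kind.order
        assert all(r in (0, 1) and c in (0, 1) for r, c in offs)
    with pytest.raises(TypeError):
        glider_offsets("alpha")


def test_measure_statistic_hand_enumeration():
    """Brute-force oracle: 6 horizontal spin pairs of a fixed 3x3 image."""
    tex = Texture(np.array([[1, 0, 1], [0, 0, 1], [1, 1, 0]]))
    # spins: (+-+)(--+)(++-); pair products: -1,-1, +1,-1, +1,-1 -> mean -1/3
    assert measure_statistic(tex, GliderKind.BETA_H) == pytest.approx(-1 / 3)


def test_measure_statistic_checkerboard_and_uniform():
    cb = Texture(np.indices((4, 4)).sum(axis=0) % 2)
    assert measure_statistic(cb, GliderKind.BETA_H) == -1.0
    assert measure_statistic(cb, GliderKind.ALPHA) == 1.0
    white = Texture(np.ones((4, 4), dtype=int))
    for kind in ALL_KINDS:
        assert measure_statistic(white, kind) == 1.0


def test_measure_statistic_too_small():
    with pytest.raises(ValueError, match="smaller"):
        measure_statistic(Texture(np.ones((1, 3), dtype=int)), GliderKind.ALPHA)


def test_statistic_profile_all_black_parity():
    """All-black image: spin products are (-1)^order."""
    prof = statistic_profile(Texture(np.zeros((5, 7), dtype=int)))
    for kind in EVEN_KINDS:
        assert prof[kind] == 1.0
    for kind in ODD_KINDS:
        assert prof[kind] == -1.0


def test_white_noise_profile_near_zero():
    tex = generate_texture(TextureSpec(GliderKind.GAMMA, 0.0, seed=5))
    for kind, val in statistic_profile(tex).items():
        assert abs(val) < 0.2, kind


@settings(max_examples=40, derandomize=True)
@given(kind=st.sampled_from(ALL_KINDS), sign=st.sampled_from([1.0, -1.0]),
       seed=st.integers(0, 2**16))
def test_extreme_intensity_forces_parity(kind, sign, seed):
    """|intensity| = 1 fixes the parity of every glider placement exactly."""
    tex = generate_texture(TextureSpec(kind, sign, height=10, width=13,
                                       seed=seed))
    assert measure_statistic(tex, kind) == sign


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_calibration_smoke(kind):
    """Ensemble mean of the matching statistic tracks the requested
    intensity (small-sample version of the full calibration check)."""
    g = 0.85 if kind.order <= 2 else 0.95
    vals = [measure_statistic(
        generate_texture(TextureSpec(kind, g, seed=1000 + i)), kind)
        for i in range(60)]
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean() - g) < max(3 * se, 5e-3)


def test_off_target_statistics_theta():
    """Theta textures carry no 1- or 2-point structure."""
    others = [GliderKind.GAMMA] + [k for k in EVEN_KINDS if k != GliderKind.ALPHA]
    for target in (GliderKind.THETA_TL, GliderKind.THETA_BR):
        vals = {k: [] for k in others}
        for i in range(100):
            tex = generate_texture(TextureSpec(target, 0.9, seed=i))
            for k in others:
                vals[k].append(measure_statistic(tex, k))
        for k, v in vals.items():
            v = np.asarray(v)
            se = v.std(ddof=1) / np.sqrt(v.size)
            assert abs(v.mean()) < max(3 * se, 5e-3), (target, k)


def test_beta_rows_factorize_into_alpha():
    """Independent rows: the 2x2 product expectation is the square of the
    row-pair expectation."""
    g = 0.6
    vals = [measure_statistic(
        generate_texture(TextureSpec(GliderKind.BETA_H, g, seed=i)),
        GliderKind.ALPHA) for i in range(300)]
    vals = np.asarray(vals)
    se = vals.std(ddof=1) / np.sqrt(vals.size)
    assert abs(vals.mean() - g**2) < 3 * se + 1e-3


def test_determinism_and_seed_variation():
    spec = TextureSpec(GliderKind.THETA_TR, -0.4, seed=11)
    assert generate_texture(spec) == generate_texture(spec)
    other = generate_texture(TextureSpec(GliderKind.THETA_TR, -0.4, seed=12))
    assert generate_texture(spec) != other


def test_spec_validation():
    with pytest.raises(ValueError, match="intensity"):
        TextureSpec(GliderKind.ALPHA, 1.2)
    with pytest.raises(ValueError, match="too small"):
        TextureSpec(GliderKind.ALPHA, 0.5, height=1, width=10)
    # order-1 glider is fine on a single row
    generate_texture(TextureSpec(GliderKind.GAMMA, 0.5, height=1, width=10))


@pytest.mark.parametrize("fmt", ["pbm", "png"])
def test_roundtrip(tmp_path, fmt):
    tex = generate_texture(TextureSpec(GliderKind.ALPHA, 0.95, seed=3))
    path = tmp_path / f"t.{fmt}"
    write_texture(tex, path)
    assert read_texture(path) == tex


def test_pbm_all_white_body(tmp_path):
    """PBM uses 1 = black, so an all-white image is written as zeros."""
    path = tmp_path / "w.pbm"
    write_texture(Texture(np.ones((2, 2), dtype=int)), path)
    body = path.read_text().splitlines()[2:]
    assert " ".join(body).split() == ["0"] * 4


@pytest.mark.parametrize("content, msg", [
    ("P4\n2 2\n0 0\n0 0\n", "magic"),
    ("P1\n2\n", "truncated"),
    ("P1\n2 2\n0 1 1\n", "expected 4 pixels"),
    ("P1\n2 2\n0 1 2 1\n", "invalid pixel"),
])
def test_pbm_parse_errors(tmp_path, content, msg):
    path = tmp_path / "bad.pbm"
    path.write_text(content)
    with pytest.raises(TextureParseError, match=msg):
        read_texture(path)
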