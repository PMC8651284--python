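"""Maximum-entropy binary textures with controlled multipoint correlations.

A *glider* is a template of 1-4 cells inside a 2x2 bounding box. The texture
statistic associated with a glider is the expectation, over all fully
in-bounds placements of the glider on a binary image, of the product of the
spin values (white = +1, black = -1) at the glider cells. A statistic value
("intensity") of 0 is white noise; +1 (-1) forces even (odd) parity of every
placement.

For each glider kind, :func:`generate_texture` samples from the
maximum-entropy ensemble of binary images with the requested mean statistic:

* 1-point (gamma): i.i.d. pixels with P(white) = (1 + g) / 2;
* 2-point (beta): independent 1-D Markov chains along the glider's axis,
  fair seed, each spin repeating its predecessor with probability
  (1 + g) / 2;
* 3-point (theta) and 4-point (alpha): fair first row and column, remaining
  cells filled in raster order so the product of spins across each glider
  placement is an independent +-1 sign with P(+1) = (1 + g) / 2.

These constructions make the parity of every glider placement an i.i.d.
coin, so the measured statistic concentrates on the requested intensity and
all lower-order statistics stay at zero.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
from PIL import Image

__all__ = [
    "GliderKind",
    "TextureSpec",
    "Texture",
    "TextureParseError",
    "glider_offsets",
    "generate_texture",
    "measure_statistic",
    "statistic_profile",
    "write_texture",
    "read_texture",
]


class GliderKind(Enum):
    """The ten glider templates: 1-, 2-, 3- and 4-point correlations."""

    GAMMA = "gamma"
    BETA_H = "beta_h"
    BETA_V = "beta_v"
    BETA_DMAIN = "beta_dmain"
    BETA_DANTI = "beta_danti"
    THETA_TL = "theta_tl"
    THETA_TR = "theta_tr"
    THETA_BL = "theta_bl"
    THETA_BR = "theta_br"
    ALPHA = "alpha"

    @property
    def offsets(self) -> tuple[tuple[int, int], ...]:
        return _OFFSETS[self]

    @property
    def order(self) -> int:
        """Number of cells in the glider (1-4)."""
        return len(_OFFSETS[self])


# (row, col) cell offsets within the 2x2 bounding box; row grows downward.
# THETA_* is named after the omitted corner of the 2x2 box.
_OFFSETS: dict[GliderKind, tuple[tuple[int, int], ...]] = {
    GliderKind.GAMMA: ((0, 0),),
    GliderKind.BETA_H: ((0, 0), (0, 1)),
    GliderKind.BETA_V: ((0, 0), (1, 0)),
    GliderKind.BETA_DMAIN: ((0, 0), (1, 1)),
    GliderKind.BETA_DANTI: ((0, 1), (1, 0)),
    GliderKind.THETA_TL: ((0, 1), (1, 0), (1, 1)),
    GliderKind.THETA_TR: ((0, 0), (1, 0), (1, 1)),
    GliderKind.THETA_BL: ((0, 0), (0, 1), (1, 1)),
    GliderKind.THETA_BR: ((0, 0), (0, 1), (1, 0)),
    GliderKind.ALPHA: ((0, 0), (0, 1), (1, 0), (1, 1)),
}


def glider_offsets(kind: GliderKind) -> list[tuple[int, int]]:
    """Canonical (row, col) cell offsets of a glider within its 2x2 box."""
    if not isinstance(kind, GliderKind):
        raise TypeError(f"not a GliderKind: {kind!r}")
    return list(_OFFSETS[kind])


@dataclass(frozen=True)
class TextureSpec:
    """Recipe for one maximum-entropy texture.

    Parameters
    ----------
    glider : GliderKind
        Which multipoint statistic to control.
    intensity : float
        Signed statistic level in [-1, 1]; 0 is white noise.
    height, width : int
        Image size in pixels. Defaults match the 39 x 22 stimulus frame.
    seed : int or None
        Seed for the texture's private random stream.
    """

    glider: GliderKind
    intensity: float
    height: int = 22
    width: int = 39
    seed: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.glider, GliderKind):
            raise TypeError(f"glider must be a GliderKind, got {self.glider!r}")
        if abs(self.intensity) > 1:
            raise ValueError(f"|intensity| must be <= 1, got {self.intensity}")
        min_dim = 1 if self.glider.order == 1 else 2
        if self.height < min_dim or self.width < min_dim:
            raise ValueError(
                f"texture size {self.height}x{self.width} too small for "
                f"order-{self.glider.order} glider"
            )


@dataclass(frozen=True)
class Texture:
    """A binary image: pixels in {0, 1} with 0 = black, 1 = white."""

    pixels: np.ndarray
    spec: TextureSpec | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("pixel values must be exactly 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def spins(self) -> np.ndarray:
        """Spin view z = 2*pixel - 1 in {-1, +1} (white = +1)."""
        return 2 * self.pixels.astype(np.int8) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Texture):
            return NotImplemented
        return self.pixels.shape == other.pixels.shape and bool(
            (self.pixels == other.pixels).all()
        )


def _signs(rng: np.random.Generator, shape, p_plus: float) -> np.ndarray:
    """+-1 array with P(+1) = p_plus."""
    return np.where(rng.random(shape) < p_plus, 1, -1).astype(np.int8)


def _beta_chains(rng: np.random.Generator, n_chains: int, length: int,
                 p_same: float) -> np.ndarray:
    """Independent +-1 Markov chains as rows: fair seed, then repeat each
    spin with probability p_same."""
    seed = _signs(rng, (n_chains, 1), 0.5)
    if length == 1:
        return seed
    same = np.where(rng.random((n_chains, length - 1)) < p_same, 1, -1)
    return np.cumprod(np.concatenate([seed, same], axis=1), axis=1).astype(np.int8)


def _generate_spins(spec: TextureSpec, rng: np.random.Generator) -> np.ndarray:
    g = spec.intensity
    h, w = spec.height, spec.width
    p = (1.0 + g) / 2.0
    kind = spec.glider

    if kind is GliderKind.GAMMA:
        return _signs(rng, (h, w), p)

    if kind is GliderKind.BETA_H:
        return _beta_chains(rng, h, w, p)
    if kind is GliderKind.BETA_V:
        return _beta_chains(rng, w, h, p).T
    if kind in (GliderKind.BETA_DMAIN, GliderKind.BETA_DANTI):
        # Main-diagonal chains; the anti-diagonal ensemble is its mirror.
        z = np.empty((h, w), dtype=np.int8)
        for k in range(-(h - 1), w):
            length = len(np.diagonal(z, offset=k))
            chain = _beta_chains(rng, 1, length, p)[0]
            i0, j0 = (0, k) if k >= 0 else (-k, 0)
            idx = np.arange(length)
            z[i0 + idx, j0 + idx] = chain
        if kind is GliderKind.BETA_DANTI:
            z = z[:, ::-1]
        return np.ascontiguousarray(z)

    # Orders 3 and 4: fair first row and column, raster fill. THETA_BR has
    # no cell at (1,1), so its ensemble is the left-right flip of THETA_BL.
    flip = kind is GliderKind.THETA_BR
    fill_kind = GliderKind.THETA_BL if flip else kind

    z = np.empty((h, w), dtype=np.int8)
    z[0, :] = _signs(rng, w, 0.5)
    z[1:, 0] = _signs(rng, h - 1, 0.5)
    r = np.where(rng.random((h - 1, w - 1)) < p, 1, -1)
    for i in range(1, h):
        prev = z[i - 1]
        ri = r[i - 1]
        if fill_kind is GliderKind.THETA_BL:
            # new cell (i,j) paired with (i-1,j-1) and (i-1,j): no recursion
            z[i, 1:] = prev[:-1] * prev[1:] * ri
        elif fill_kind is GliderKind.THETA_TL:
            # paired with (i-1,j) and (i,j-1): cumulative along the row
            z[i, 1:] = z[i, 0] * np.cumprod(prev[1:] * ri)
        elif fill_kind is GliderKind.THETA_TR:
            # paired with (i-1,j-1) and (i,j-1)
            z[i, 1:] = z[i, 0] * np.cumprod(prev[:-1] * ri)
        elif fill_kind is GliderKind.ALPHA:
            z[i, 1:] = z[i, 0] * np.cumprod(prev[1:] * prev[:-1] * ri)
        else:  # pragma: no cover
            raise AssertionError(fill_kind)
    if flip:
        z = np.ascontiguousarray(z[:, ::-1])
    return z


def generate_texture(spec: TextureSpec) -> Texture:
    """Sample one maximum-entropy texture according to ``spec``.

    Deterministic given ``spec.seed``: all random draws come from a single
    seeded stream consumed in a fixed (raster) order.
    """
    rng = np.random.default_rng(spec.seed)
    spins = _generate_spins(spec, rng)
    return Texture(pixels=((spins + 1) // 2).astype(np.uint8), spec=spec)


def measure_statistic(tex: Texture, kind: GliderKind) -> float:
    """Empirical glider statistic of a texture.

    The average, over all fully in-bounds glider placements, of the product
    of spin values at the glider cells; always in [-1, 1].
    """
    offs = glider_offsets(kind)
    gh = max(r for r, _ in offs) + 1
    gw = max(c for _, c in offs) + 1
    h, w = tex.shape
    if h < gh or w < gw:
        raise ValueError(
            f"texture {h}x{w} smaller than {gh}x{gw} glider bounding box"
        )
    z = tex.spins.astype(np.int64)
    out = np.ones((h - gh + 1, w - gw + 1), dtype=np.int64)
    for r, c in offs:
        out *= z[r:r + h - gh + 1, c:c + w - gw + 1]
    return float(out.mean())


def statistic_profile(tex: Texture) -> dict[GliderKind, float]:
    """All ten glider statistics of one texture."""
    return {kind: measure_statistic(tex, kind) for kind in GliderKind}


class TextureParseError(ValueError):
    """Raised when a texture file cannot be parsed."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pbm", "png"):
            raise ValueError(f"unsupported texture format: {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".pbm":
        return "pbm"
    if suffix == ".png":
        return "png"
    raise ValueError(f"cannot infer texture format from {path.name!r}")


def write_texture(tex: Texture, path: str | Path, fmt: str | None = None) -> None:
    """Write a texture as plain PBM (P1, 1 = black) or 8-bit grayscale PNG
    (white = 255, black = 0)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "pbm":
        h, w = tex.shape
        lines = [f"P1", f"{w} {h}"]
        bits = 1 - tex.pixels  # PBM convention: 1 = black
        lines += [" ".join(str(int(b)) for b in row) for row in bits]
        path.write_text("\n".join(lines) + "\n")
    else:
        img = Image.fromarray((tex.pixels * np.uint8(255)), mode="L")
        img.save(path, format="PNG")


def _parse_pbm(text: str, name: str) -> np.ndarray:
    # strip comments, then tokenize
    tokens: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0]
        tokens.extend((tok, lineno) for tok in body.split())  # type: ignore[arg-type]
    if not tokens:
        raise TextureParseError(f"{name}: empty PBM file")
    if tokens[0][0] != "P1":
        raise TextureParseError(
            f"{name}: line {tokens[0][1]}: expected magic 'P1', got {tokens[0][0]!r}"
        )
    vals = tokens[1:]
    if len(vals) < 2:
        raise TextureParseError(f"{name}: truncated header (missing dimensions)")
    try:
        w, h = int(vals[0][0]), int(vals[1][0])
    except ValueError as exc:
        raise TextureParseError(f"{name}: bad dimension token: {exc}") from None
    if w <= 0 or h <= 0:
        raise TextureParseError(f"{name}: nonpositive dimensions {w}x{h}")
    data = vals[2:]
    if len(data) < w * h:
        raise TextureParseError(
            f"{name}: expected {w * h} pixels, found {len(data)}"
        )
    bits = np.empty(w * h, dtype=np.uint8)
    for i, (tok, lineno) in enumerate(data[: w * h]):
        if tok == "0":
            bits[i] = 0
        elif tok == "1":
            bits[i] = 1
        else:
            raise TextureParseError(
                f"{name}: line {lineno}: invalid pixel token {tok!r}"
            )
    return (1 - bits).reshape(h, w)  # PBM 1 = black -> pixel 0


def read_texture(path: str | Path, fmt: str | None = None) -> Texture:
    """Read a texture written by :func:`write_texture`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "pbm":
        return Texture(pixels=_parse_pbm(path.read_text(), path.name))
    try:
        arr = np.asarray(Image.open(path).convert("L"))
    except Exception as exc:
        raise TextureParseError(f"{path.name}: not a readable PNG: {exc}") from exc
    if not np.isin(arr, (0, 255)).all():
        raise TextureParseError(
            f"{path.name}: PNG contains gray values other than 0 and 255"
        )
    return Texture(pixels=(arr // 255).astype(np.uint8))
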