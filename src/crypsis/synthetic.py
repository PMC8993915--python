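"""Seeded synthetic-data generators for every pipeline stage.

Each generator emulates the statistical structure its consuming stage
assumes, with known ground truth, so the whole pipeline is testable
without any external download:

- :func:`gen_morpho` — a two-group morphometric table whose per-variable
  medians and ranges default to the published comparison table of the
  Nearctic cryptic species versus the Palearctic look-alike complex
  (triangular distributions, mode at the median, clipped to the printed
  range; size correlation induced by sampling head size CS first and
  deriving absolute lengths from sampled size-corrected ratios);
- :func:`gen_alignment` — barcode alignments realizing a requested number
  of mitotypes, frequency profile and pairwise divergences exactly;
- :func:`gen_niche` — environmental layer stacks with occurrence labels
  drawn Bernoulli from a known logistic suitability surface;
- :func:`gen_images` — lateral "mesosoma profile" silhouettes with
  group-specific propodeum height and per-specimen affine jitter.

One integer seed fans out to independent per-generator streams through
fixed offsets, so the same seed reproduces every stage byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from skimage import transform as sktransform

from crypsis.barcode import BarcodeAlignment, SequenceRecord
from crypsis.enm import EnvGrid, EnmError, OccurrenceSet, extract_covariates

__all__ = [
    "TABLE1_PARAMS",
    "MorphoSimSpec",
    "AlignmentSimSpec",
    "NicheSimSpec",
    "ImageSimSpec",
    "gen_morpho",
    "gen_alignment",
    "gen_niche",
    "gen_images",
]

# stream offsets for the seed fan-out
_OFFSETS = {"morpho": 101, "alignment": 202, "niche": 303, "images": 404}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _OFFSETS[stage]])


# ---------------------------------------------------------------------------
# morphometrics

#: Published two-group medians and ranges (median, low, high) per variable.
#: Absolute head lengths in mm, sqPDCL in µm, setae raw counts; appendage
#: lengths are parameterized through their size-corrected ratios so that
#: generated specimens carry realistic size correlation.
TABLE1_PARAMS = {
    "CS": {"nearctic": (0.84, 0.70, 0.94), "palearctic": (0.95, 0.71, 1.12)},
    "CL/CW": {"nearctic": (1.077, 1.026, 1.143), "palearctic": (1.062, 0.997, 1.162)},
    "SL/CS": {"nearctic": (0.97, 0.92, 1.03), "palearctic": (0.98, 0.90, 1.06)},
    "EYE/CS": {"nearctic": (0.239, 0.220, 0.259), "palearctic": (0.237, 0.213, 0.266)},
    "GuHL/CS": {"nearctic": (0.117, 0.071, 0.150), "palearctic": (0.084, 0.055, 0.128)},
    "dClAn/CS": {"nearctic": (0.044, 0.026, 0.056), "palearctic": (0.051, 0.042, 0.061)},
    "MP6/CS": {"nearctic": (0.161, 0.133, 0.206), "palearctic": (0.174, 0.136, 0.229)},
    "PnHL/CS": {"nearctic": (0.134, 0.090, 0.190), "palearctic": (0.127, 0.067, 0.171)},
    "PoOc/CL": {"nearctic": (0.242, 0.212, 0.262), "palearctic": (0.244, 0.209, 0.271)},
    "sqPDCL": {"nearctic": (5.47, 3.90, 7.37), "palearctic": (4.25, 3.58, 6.11)},
    "PLF": {"nearctic": (0.034, 0.026, 0.048), "palearctic": (0.028, 0.021, 0.041)},
    "nGen": {"nearctic": (13, 5, 19), "palearctic": (8.5, 3, 18)},
    "nGu": {"nearctic": (13, 4, 24), "palearctic": (8, 2, 25)},
    "nHT": {"nearctic": (26, 11, 35), "palearctic": (18, 6, 39)},
    "nOcc": {"nearctic": (18.5, 9, 26), "palearctic": (16, 7, 25)},
    "nSc": {"nearctic": (25, 4, 39), "palearctic": (18, 10, 36)},
    "nSt": {"nearctic": (7, 4, 11), "palearctic": (4, 0, 10)},
}

#: probability that the offset mandibular denticle is scored present
MADE_PRESENT = {"nearctic": 0.81, "palearctic": 1.0}

_COUNT_VARS = {"nGen", "nGu", "nHT", "nOcc", "nSc", "nSt"}


@dataclass
class MorphoSimSpec:
    """Two-group morphometric simulation design."""

    n_nearctic: int = 39
    n_palearctic: int = 49
    params: dict = field(default_factory=lambda: TABLE1_PARAMS)
    made_present: dict = field(default_factory=lambda: dict(MADE_PRESENT))
    scale: float = 1.0  # multiplies within-group spread; 0 = all at medians
    seed: int = 0

    def __post_init__(self):
        if self.n_nearctic < 2 or self.n_palearctic < 2:
            raise ValueError("need n >= 2 per group")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        for var, groups in self.params.items():
            for g, (mode, lo, hi) in groups.items():
                if not lo <= mode <= hi or lo == hi and mode != lo:
                    raise ValueError(f"invalid range for {var}/{g}: {(mode, lo, hi)}")


def _triangular(rng, med, lo, hi, n, scale):
    """Split-triangular sample with its population median at ``med``.

    The printed tables give medians and ranges only; each side of the
    median carries half the mass with a linearly decaying density to the
    range end.  ``scale`` shrinks the range around the median (0 =
    degenerate at the median).
    """
    if scale == 0 or lo == hi:
        return np.full(n, float(med))
    a = med - scale * (med - lo)
    b = med + scale * (hi - med)
    # split triangular: half the mass on each side of the median, density
    # peaking at the median and falling linearly to each range end; this
    # pins the population median at the printed value for arbitrarily
    # skewed printed ranges
    left = rng.random(n) < 0.5
    out = np.empty(n)
    out[left] = rng.triangular(a, med, med, size=int(left.sum())) if med > a else a
    out[~left] = rng.triangular(med, med, b, size=int((~left).sum())) if b > med else b
    return out


def gen_morpho(spec: MorphoSimSpec) -> pd.DataFrame:
    """Generate a specimen table with the 19-variable measurement scheme.

    Deterministic given the seed; the ``group`` column is the ground-truth
    label.
    """
    rng = _rng(spec.seed, "morpho")
    frames = []
    for group, n in (("nearctic", spec.n_nearctic), ("palearctic", spec.n_palearctic)):
        draws = {
            var: _triangular(rng, *spec.params[var][group], n, spec.scale)
            for var in spec.params
        }
        cs = draws["CS"]
        r = draws["CL/CW"]
        df = pd.DataFrame({
            "specimen_id": [f"{group[:3]}_{i:03d}" for i in range(n)],
            "group": group,
            "CS": cs,
            "CL": 2 * cs * r / (1 + r),
            "CW": 2 * cs / (1 + r),
            "SL": draws["SL/CS"] * cs,
            "EYE": draws["EYE/CS"] * cs,
            "GuHL": draws["GuHL/CS"] * cs,
            "dClAn": draws["dClAn/CS"] * cs,
            "MP6": draws["MP6/CS"] * cs,
            "PnHL": draws["PnHL/CS"] * cs,
            "sqPDCL": draws["sqPDCL"],
            "PLF": draws["PLF"],
            "MaDe": np.where(
                rng.random(n) < spec.made_present[group], "present", "absent"
            ),
        })
        df["PoOc"] = draws["PoOc/CL"] * df["CL"]
        for var in sorted(_COUNT_VARS):
            df[var] = np.clip(np.round(draws[var]), 0, None).astype(int)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# barcode alignments

#: mitotype count profile of a diverse barcode sample: one moderately
#: common type plus a tail of rare types (n = 28, k = 15, Nei h ≈ 0.899)
DEEP_LINEAGE_COUNTS = (8, 4, 3, 2, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1)
#: per-haplotype substitution counts from the reference realizing four
#: depth classes: a shallow cluster around the reference, two mid-depth
#: types and two deep types whose pair attains 39/658 ≈ 5.9% divergence
DEEP_LINEAGE_DIVERGENCES = (1, 2, 3, 19, 20, 2, 3, 11, 10, 2, 3, 10, 11, 5)

#: dominance profile of a genetically uniform, widespread species
#: (n = 70, k = 7, Nei h ≈ 0.682, max pairwise 4 subs = 0.6%)
LOW_DIVERSITY_COUNTS = (35, 16, 10, 4, 2, 2, 1)
LOW_DIVERSITY_DIVERGENCES = (1, 1, 1, 1, 2, 2)


@dataclass
class AlignmentSimSpec:
    """Barcode-alignment simulation design.

    ``divergences[i]`` is the exact number of substituted sites between
    haplotype i+2 and haplotype 1; substitution site sets are disjoint, so
    the divergence between haplotypes i, j > 1 is the sum of their counts.
    Defaults emulate a diverse 28-sequence COI sample with 15 mitotypes in
    four depth classes.
    """

    n: int = 28
    L: int = 658
    k: int = 15
    frequencies: tuple | None = None  # None → study-design profiles / uniform
    divergences: tuple | None = None  # None → study-design profiles / 1,2,3,...
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.k <= self.n:
            raise ValueError("need 1 <= k <= n")
        if self.frequencies is None:
            if self.k == len(DEEP_LINEAGE_COUNTS) and self.n == sum(DEEP_LINEAGE_COUNTS):
                self.frequencies = tuple(c / self.n for c in DEEP_LINEAGE_COUNTS)
            elif self.k == len(LOW_DIVERSITY_COUNTS) and self.n == sum(LOW_DIVERSITY_COUNTS):
                self.frequencies = tuple(c / self.n for c in LOW_DIVERSITY_COUNTS)
        if self.divergences is None:
            if self.k == 15:
                self.divergences = DEEP_LINEAGE_DIVERGENCES
            elif self.k == 7:
                self.divergences = LOW_DIVERSITY_DIVERGENCES
            else:
                self.divergences = tuple(range(1, self.k))
        f = np.asarray(self.frequencies, float) if self.frequencies is not None else None
        if f is not None and (len(f) != self.k or abs(f.sum() - 1.0) > 1e-9 or np.any(f <= 0)):
            raise ValueError("frequencies must be k positive values summing to 1")
        if len(self.divergences) != self.k - 1:
            raise ValueError("need k-1 divergence counts (haplotypes 2..k vs haplotype 1)")
        if sum(self.divergences) > self.L:
            raise ValueError("total requested divergence exceeds alignment length")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @classmethod
    def deep_lineage(cls, seed: int = 0) -> "AlignmentSimSpec":
        """Diverse-sample design: 15 mitotypes in 28 sequences, 4 depth classes."""
        return cls(n=28, k=15, seed=seed)

    @classmethod
    def low_diversity(cls, seed: int = 0) -> "AlignmentSimSpec":
        """Uniform-species design: 7 mitotypes in 70 sequences, one dominant."""
        return cls(n=70, k=7, seed=seed)


def _counts_from_frequencies(freqs: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n among the frequency classes."""
    raw = freqs * n
    counts = np.floor(raw).astype(int)
    counts[counts == 0] = 1  # every haplotype must be realized
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    rem = raw - np.floor(raw)
    order = np.argsort(-rem)
    i = 0
    while counts.sum() < n:
        counts[order[i % len(order)]] += 1
        i += 1
    return counts


def gen_alignment(spec: AlignmentSimSpec):
    """Generate an alignment plus its true mitotype assignment.

    Returns ``(BarcodeAlignment, assignment)`` where ``assignment[i]`` is
    the 0-based haplotype index of record i.  Haplotypes differ from the
    reference by exactly the requested substitution counts; missing cells
    (N) are injected uniformly at ``missing_rate``.
    """
    rng = _rng(spec.seed, "alignment")
    bases = np.array(list("ACGT"))
    ref = rng.choice(bases, size=spec.L)
    divs = spec.divergences
    all_sites = rng.permutation(spec.L)
    haplotypes = [ref.copy()]
    cursor = 0
    for d in divs:
        hap = ref.copy()
        sites = all_sites[cursor:cursor + d]
        cursor += d
        for s in sites:
            choices = [b for b in "ACGT" if b != ref[s]]
            hap[s] = choices[rng.integers(0, 3)]
        haplotypes.append(hap)
    freqs = (np.asarray(spec.frequencies, float) if spec.frequencies is not None
             else np.full(spec.k, 1.0 / spec.k))
    counts = _counts_from_frequencies(freqs, spec.n)
    records, assignment = [], []
    idx = 0
    for h, cnt in enumerate(counts):
        for _ in range(cnt):
            seq = haplotypes[h].copy()
            if spec.missing_rate > 0:
                mask = rng.random(spec.L) < spec.missing_rate
                seq = np.where(mask, "N", seq)
            records.append(SequenceRecord(f"seq_{idx:03d}", "".join(seq)))
            assignment.append(h)
            idx += 1
    return BarcodeAlignment(records), np.array(assignment)


# ---------------------------------------------------------------------------
# niche landscapes

@dataclass
class NicheSimSpec:
    """Synthetic landscape with a known logistic suitability surface."""

    shape: tuple = (40, 60)
    n_layers: int = 4
    # coefficients on standardized layers; the default signal strength makes
    # the true surface discriminate presences from absences at the level a
    # well-performing niche-model suite reports (ROC comfortably above 0.9)
    coefficients: tuple = (3.0, -2.5, 0.0, 0.0)
    intercept: float = 0.0
    n_presence: int = 180
    n_absence: int = 182
    xllcorner: float = -10.0
    yllcorner: float = 35.0
    cellsize: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.shape[0] < 10 or self.shape[1] < 10:
            raise ValueError("grid must be at least 10x10")
        if len(self.coefficients) != self.n_layers:
            raise ValueError("one coefficient per layer required")
        if self.n_presence < 1 or self.n_absence < 1:
            raise ValueError("both classes must be requested")


def _smooth_layer(rng, shape):
    """A smooth field: random linear gradient + low-frequency sinusoid + noise."""
    nrows, ncols = shape
    rr, cc = np.meshgrid(np.linspace(0, 1, nrows), np.linspace(0, 1, ncols), indexing="ij")
    a, b = rng.normal(size=2)
    ph1, ph2 = rng.uniform(0, 2 * math.pi, size=2)
    f1, f2 = rng.uniform(1.0, 3.0, size=2)
    layer = (a * rr + b * cc
             + 0.8 * np.sin(2 * math.pi * f1 * rr + ph1)
             + 0.8 * np.sin(2 * math.pi * f2 * cc + ph2)
             + 0.15 * rng.normal(size=shape))
    return (layer - layer.mean()) / layer.std()


def gen_niche(spec: NicheSimSpec):
    """Generate (EnvGrid, OccurrenceSet, true probability surface).

    Labels are Bernoulli draws from the true logistic surface at each
    sampled cell; sampling continues until the requested presence and
    absence counts are both reached.
    """
    rng = _rng(spec.seed, "niche")
    shape = tuple(spec.shape)
    layers = {f"env_{j:02d}": _smooth_layer(rng, shape) for j in range(spec.n_layers)}
    names = sorted(layers)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.allclose(layers[a], layers[b]):
                raise EnmError(f"degenerate all-equal layers {a} and {b}")
    stack = np.stack([layers[nm] for nm in sorted(layers)], axis=-1)
    eta = spec.intercept + stack @ np.asarray(spec.coefficients, float)
    true_prob = expit(eta)

    grid = EnvGrid(layers, spec.xllcorner, spec.yllcorner, spec.cellsize)
    nrows, ncols = shape
    lon, lat, label = [], [], []
    n_pres = n_abs = 0
    max_draws = 1000 * (spec.n_presence + spec.n_absence)
    for _ in range(max_draws):
        if n_pres >= spec.n_presence and n_abs >= spec.n_absence:
            break
        r = int(rng.integers(0, nrows))
        c = int(rng.integers(0, ncols))
        y = int(rng.random() < true_prob[r, c])
        if y == 1 and n_pres >= spec.n_presence:
            continue
        if y == 0 and n_abs >= spec.n_absence:
            continue
        lon.append(spec.xllcorner + (c + 0.5) * spec.cellsize)
        lat.append(spec.yllcorner + (nrows - r - 0.5) * spec.cellsize)
        label.append("presence" if y else "absence")
        n_pres += y
        n_abs += 1 - y
    else:
        raise EnmError("could not realize the requested class counts; surface too extreme")
    points = pd.DataFrame({"lon": lon, "lat": lat, "label": label})
    occ = extract_covariates(grid, points)
    return grid, occ, true_prob


# ---------------------------------------------------------------------------
# profile images

@dataclass
class ImageSimSpec:
    """Mesosoma-silhouette image simulation design.

    The silhouette is a filled profile whose upper outline is the sum of a
    pronotum bump and a propodeum dome; ``propodeum_ratio`` (dome height /
    pronotum height) is the group-level shape parameter the averaging
    stage is meant to recover.
    """

    canvas: tuple = (80, 120)
    n: int = 35
    pronotum_height: float = 22.0  # px
    propodeum_ratio: float = 0.7
    body_length: float = 80.0  # px
    jitter_scale: float = 0.02  # sd of the per-specimen scale factor
    jitter_shift: float = 1.0  # sd (px) of the per-specimen translation
    seed: int = 0

    def __post_init__(self):
        H, W = self.canvas
        if self.body_length >= W or self.pronotum_height * (1 + self.propodeum_ratio) >= H:
            raise ValueError("silhouette does not fit the canvas")


def _silhouette(spec: ImageSimSpec) -> np.ndarray:
    """Noise-free group-mean silhouette (black = 0 on white = 1)."""
    H, W = spec.canvas
    img = np.ones((H, W))
    x0 = (W - spec.body_length) / 2.0
    baseline = int(H * 0.75)
    xs = np.arange(W)
    u = (xs - x0) / spec.body_length  # 0..1 along the mesosoma
    height = np.where(
        (u >= 0) & (u <= 1),
        spec.pronotum_height * (
            np.exp(-0.5 * ((u - 0.25) / 0.12) ** 2)
            + spec.propodeum_ratio * np.exp(-0.5 * ((u - 0.78) / 0.10) ** 2)
            + 0.25
        ),
        0.0,
    )
    for x in xs:
        h = int(round(height[x]))
        if h > 0:
            img[baseline - h:baseline, x] = 0.0
    return img


def gen_images(spec: ImageSimSpec):
    """Generate jittered silhouette images plus the true mean silhouette.

    Each image is the group silhouette under a small random affine
    transform (isotropic scale jitter around 1 and a pixel-scale
    translation), out-of-canvas regions white.
    """
    rng = _rng(spec.seed, "images")
    base = _silhouette(spec)
    H, W = spec.canvas
    images = []
    for _ in range(spec.n):
        s = 1.0 + rng.normal(0.0, spec.jitter_scale)
        dy, dx = rng.normal(0.0, spec.jitter_shift, size=2)
        center = np.array([W / 2.0, H / 2.0])
        shift = center - s * center + np.array([dx, dy])
        tform = sktransform.AffineTransform(scale=(s, s), translation=shift)
        img = sktransform.warp(base, tform.inverse, output_shape=(H, W),
                               order=1, mode="constant", cval=1.0)
        images.append(np.clip(img, 0.0, 1.0))
    return images, base
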