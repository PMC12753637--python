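"""Synthetic PD-L1 IHC patch, case and cohort generation.

Real PD-L1 slide cohorts are access-controlled, so testing ground truth is
produced here: 256x256 px (configurable) RGB patches imitating the colour
structure of DAB/haematoxylin IHC — brown PD-L1-positive tumour cells, blue
PD-L1-negative tumour cells, a pale eosin-like background — together with
pixel-exact label masks (0 background, 1 positive, 2 negative) and the known
cell tally, so the downstream counting and scoring stages can be verified
against construction-time truth.

Macrophage-like distractors emulate the classic confounder of TPS scoring:
PD-L1-positive non-tumour cells "hugging" tumour clusters. They are rendered
with the positive-like DAB chromogen but smaller and darker (dense granular
staining), and are always labelled background in the mask.

Cells are ellipses placed by rejection sampling with a minimum Chebyshev
gap between cell envelopes, which guarantees that the radius-4
connected-component merge downstream never fuses two generated cells when
the gap exceeds twice the merge radius. Everything is seeded: identical
(spec, seed) pairs give bit-identical patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.draw import ellipse as _ellipse

from .quantify import CellTally, compute_tps

__all__ = [
    "PlacementError",
    "SyntheticPatchSpec",
    "SyntheticCase",
    "CohortSpec",
    "generate_patch",
    "generate_case",
    "generate_cohort",
]

# flat reference colours (8-bit RGB); see docs/methods.md
BACKGROUND_RGB = (233, 213, 218)     # eosin-like pale pink
NEGATIVE_RGB = (72, 78, 150)         # haematoxylin blue
POSITIVE_RGB = (112, 66, 30)         # DAB brown at full stain intensity
DISTRACTOR_RGB = (52, 34, 16)        # darker, denser macrophage-like DAB

MAX_PLACEMENT_ATTEMPTS = 1000


class PlacementError(RuntimeError):
    """Requested cells cannot be packed into the patch without overlap."""


@dataclass(frozen=True)
class SyntheticPatchSpec:
    height_px: int = 256
    width_px: int = 256
    n_positive: int = 0
    n_negative: int = 0
    n_distractor: int = 0
    cell_radius_range: tuple[int, int] = (5, 9)
    distractor_radius_range: tuple[int, int] = (2, 4)
    min_cell_gap_px: int = 12
    stain_intensity: float = 0.9
    noise_sd: float = 5.0
    forbid_tile_straddle: bool = False
    tile_size_px: int = 256

    def __post_init__(self):
        if self.height_px < 1 or self.width_px < 1 or self.tile_size_px < 1:
            raise ValueError("patch and tile dimensions must be positive")
        if min(self.n_positive, self.n_negative, self.n_distractor) < 0:
            raise ValueError("cell counts must be non-negative")
        lo, hi = self.cell_radius_range
        if not (0 < lo <= hi):
            raise ValueError("cell_radius_range must satisfy 0 < min <= max")
        if self.min_cell_gap_px < 0 or self.noise_sd < 0:
            raise ValueError("gap and noise must be non-negative")
        if not 0.0 <= self.stain_intensity <= 1.0:
            raise ValueError("stain_intensity must lie in [0, 1]")


@dataclass
class SyntheticCase:
    """A multi-patch case with its construction-time ground truth."""

    patches: list[tuple[np.ndarray, np.ndarray]]
    true_tally: CellTally
    true_tps: float | None
    case_id: str
    seed: int
    category: str | None = None
    per_patch_tallies: list[CellTally] = field(default_factory=list)


def _lerp(a, b, t: float) -> np.ndarray:
    return np.asarray(a, dtype=np.float64) + t * (
        np.asarray(b, dtype=np.float64) - np.asarray(a, dtype=np.float64))


def _place_centres(spec: SyntheticPatchSpec, radii: np.ndarray,
                   rng: np.random.Generator) -> list[tuple[int, int]]:
    """Rejection-sample cell centres with Chebyshev envelope separation."""
    h, w = spec.height_px, spec.width_px
    gap = spec.min_cell_gap_px
    # coarse feasibility: total separation footprint must fit the patch
    footprint = float(np.sum((2 * radii + gap) ** 2))
    if footprint > h * w:
        raise PlacementError(
            f"requested cells need ~{footprint:.0f} px^2 of separation "
            f"footprint but the patch has {h * w}")
    ts = spec.tile_size_px
    centres: list[tuple[int, int]] = []
    placed_r: list[int] = []
    for r in radii:
        r = int(r)
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            if spec.forbid_tile_straddle:
                # sample inside one tile, margin r+1 from its edges
                n_ty = max(1, -(-h // ts))
                n_tx = max(1, -(-w // ts))
                ty, tx = rng.integers(n_ty), rng.integers(n_tx)
                y0, y1 = ty * ts, min((ty + 1) * ts, h)
                x0, x1 = tx * ts, min((tx + 1) * ts, w)
            else:
                y0, y1, x0, x1 = 0, h, 0, w
            if y1 - y0 <= 2 * (r + 1) or x1 - x0 <= 2 * (r + 1):
                continue
            cy = int(rng.integers(y0 + r + 1, y1 - r - 1))
            cx = int(rng.integers(x0 + r + 1, x1 - r - 1))
            ok = all(max(abs(cy - py), abs(cx - px)) >= r + pr + gap
                     for (py, px), pr in zip(centres, placed_r))
            if ok:
                centres.append((cy, cx))
                placed_r.append(r)
                break
        else:
            raise PlacementError(
                f"could not place cell {len(centres) + 1}/{len(radii)} after "
                f"{MAX_PLACEMENT_ATTEMPTS} attempts (gap {gap} px)")
    return centres


def generate_patch(spec: SyntheticPatchSpec, seed: int
                   ) -> tuple[np.ndarray, np.ndarray, CellTally]:
    """Render one synthetic IHC patch.

    Returns ``(image, mask, tally)``: 8-bit RGB image, {0,1,2} label mask
    and the constructed :class:`CellTally` — exactly ``n_positive`` label-1
    cells and ``n_negative`` label-2 cells; distractors contribute stain to
    the image only.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                        0x5EED]))
    h, w = spec.height_px, spec.width_px
    lo, hi = spec.cell_radius_range
    dlo, dhi = spec.distractor_radius_range
    kinds = ([1] * spec.n_positive + [2] * spec.n_negative
             + [0] * spec.n_distractor)
    radii = np.concatenate([
        rng.integers(lo, hi + 1, size=spec.n_positive + spec.n_negative),
        rng.integers(dlo, min(dhi, hi) + 1, size=spec.n_distractor),
    ]).astype(int) if kinds else np.zeros(0, dtype=int)
    centres = _place_centres(spec, radii, rng)

    image = np.empty((h, w, 3), dtype=np.float64)
    image[...] = BACKGROUND_RGB
    mask = np.zeros((h, w), dtype=np.uint8)
    pos_rgb = _lerp(BACKGROUND_RGB, POSITIVE_RGB, spec.stain_intensity)
    colour = {1: pos_rgb, 2: np.asarray(NEGATIVE_RGB, dtype=np.float64),
              0: np.asarray(DISTRACTOR_RGB, dtype=np.float64)}
    for (cy, cx), a, kind in zip(centres, radii, kinds):
        ecc = rng.uniform(1.0, 2.0)
        b = max(1, int(round(a / ecc)))
        theta = rng.uniform(0.0, np.pi)
        rr, cc = _ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
        image[rr, cc] = colour[kind]
        if kind:
            mask[rr, cc] = kind
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    return image, mask, CellTally(spec.n_positive, spec.n_negative)


def generate_case(spec: SyntheticPatchSpec, n_patches: int, seed: int,
                  case_id: str = "case",
                  per_patch_counts=None) -> SyntheticCase:
    """Generate a case of ``n_patches`` patches sharing one master seed.

    ``per_patch_counts`` optionally overrides (n_positive, n_negative[,
    n_distractor]) patch by patch; otherwise every patch uses the counts in
    ``spec``. The case tally is the sum over patches and the true TPS is
    100 * positive / total (None when the case holds no tumour cells).
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    if per_patch_counts is not None and len(per_patch_counts) != n_patches:
        raise ValueError("per_patch_counts length must equal n_patches")
    sub_seeds = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xCA5E]
                                       ).generate_state(n_patches)
    patches, tallies = [], []
    for i in range(n_patches):
        pspec = spec
        if per_patch_counts is not None:
            c = per_patch_counts[i]
            pspec = replace(spec, n_positive=int(c[0]), n_negative=int(c[1]),
                            n_distractor=int(c[2]) if len(c) > 2
                            else spec.n_distractor)
        img, msk, tally = generate_patch(pspec, int(sub_seeds[i]) & 0x7FFFFFFF)
        patches.append((img, msk))
        tallies.append(tally)
    total = CellTally(sum(t.n_positive for t in tallies),
                      sum(t.n_negative for t in tallies))
    tps = compute_tps(total) if total.total > 0 else None
    return SyntheticCase(patches=patches, true_tally=total, true_tps=tps,
                         case_id=case_id, seed=int(seed),
                         per_patch_tallies=tallies)


@dataclass(frozen=True)
class CohortSpec:
    """A case cohort stratified over the clinical TPS categories.

    ``category_proportions`` orders the clinical reporting categories
    (<1%, 1-49%, >=50%); realised counts follow largest-remainder rounding
    of ``n_cases`` x proportions.
    """

    n_cases: int
    category_proportions: tuple[float, float, float] = (0.2, 0.4, 0.4)
    per_case_patch_count: int = 4
    seed: int = 0
    patch_template: SyntheticPatchSpec = field(
        default_factory=SyntheticPatchSpec)
    cells_per_patch_range: tuple[int, int] = (25, 40)
    max_distractors_per_patch: int = 1

    def __post_init__(self):
        if self.n_cases < 1 or self.per_case_patch_count < 1:
            raise ValueError("n_cases and per_case_patch_count must be >= 1")
        p = np.asarray(self.category_proportions, dtype=np.float64)
        if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("category_proportions must be three non-negative "
                             "reals summing to 1")
        lo, hi = self.cells_per_patch_range
        if not (0 < lo <= hi):
            raise ValueError("cells_per_patch_range must satisfy 0 < min <= max")


CATEGORY_NAMES = ("<1%", "1-49%", ">=50%")


def _largest_remainder(n: int, proportions) -> list[int]:
    raw = np.asarray(proportions, dtype=np.float64) * n
    counts = np.floor(raw).astype(int)
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(n - counts.sum()):
        counts[order[i % 3]] += 1
    return counts.tolist()


def _positive_count_range(total: int, category: int) -> tuple[int, int]:
    """Integer n_positive range realising a TPS in the clinical category."""
    lo1 = int(np.ceil(total / 100.0))          # smallest count giving >= 1%
    lo50 = int(np.ceil(total / 2.0))           # smallest count giving >= 50%
    ranges = {0: (0, lo1 - 1), 1: (max(lo1, 1), lo50 - 1), 2: (lo50, total)}
    lo, hi = ranges[category]
    if lo > hi:
        raise ValueError(
            f"category {CATEGORY_NAMES[category]} unreachable with "
            f"{total} cells per case; increase cells_per_patch_range")
    return lo, hi


def generate_cohort(cohort: CohortSpec) -> list[SyntheticCase]:
    """Generate the stratified synthetic cohort described by ``cohort``."""
    rng = np.random.default_rng(np.random.SeedSequence(
        [int(cohort.seed) & 0x7FFFFFFF, 0xC0407]))
    counts = _largest_remainder(cohort.n_cases, cohort.category_proportions)
    categories = [c for c, k in enumerate(counts) for _ in range(k)]
    lo, hi = cohort.cells_per_patch_range
    cases = []
    for i, cat in enumerate(categories):
        per_patch_total = rng.integers(lo, hi + 1,
                                       size=cohort.per_case_patch_count)
        total = int(per_patch_total.sum())
        p_lo, p_hi = _positive_count_range(total, cat)
        n_pos = int(rng.integers(p_lo, p_hi + 1))
        # scatter the positive cells uniformly over the cell slots
        slots = np.repeat(np.arange(cohort.per_case_patch_count),
                          per_patch_total)
        pos_slots = rng.choice(slots.size, size=n_pos, replace=False)
        pos_per_patch = np.bincount(slots[pos_slots],
                                    minlength=cohort.per_case_patch_count)
        counts_pp = [(int(p), int(t - p),
                      int(rng.integers(0, cohort.max_distractors_per_patch + 1)))
                     for p, t in zip(pos_per_patch, per_patch_total)]
        case_seed = int(rng.integers(0, 2**31 - 1))
        case = generate_case(cohort.patch_template,
                             cohort.per_case_patch_count, case_seed,
                             case_id=f"case_{i:03d}",
                             per_patch_counts=counts_pp)
        case.category = CATEGORY_NAMES[cat]
        cases.append(case)
    return cases
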