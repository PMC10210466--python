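"""Ground-truthed synthetic data for both pipeline arms.

Two generators are provided:

* fluorescence fields — cell-shaped bright regions (discs with a 2-px
  cosine-tapered edge) on a noisy background, with sub-threshold debris
  and, for viability fields, a known live/dead partition;
* protein abundance matrices — log-normal baselines, per-protein
  variances drawn from a scaled inverse-chi-square prior (the model the
  empirical-Bayes moderated t-test assumes), a spiked differentially
  abundant fraction, and intensity-dependent (low-abundance) missingness
  so minimum-anchored imputation is the appropriate counterpart.

Every generator draws all randomness from one ``numpy`` Generator seeded
per call; a fixed seed yields bit-identical output. Truth objects record
everything needed to score downstream stages (masks, centers, per-cell
channel means, live/dead labels, true variances, DE labels, fold
changes, missingness masks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .exceptions import PlacementError
from .field import FieldImage

EDGE_TAPER_PX = 2.0  # cosine taper width at every disc boundary
SMALL_COMPONENT_AREA = 5000  # px; the segmentation small-object cutoff


# ---------------------------------------------------------------------------
# imaging side
# ---------------------------------------------------------------------------

def _default_flux_channels() -> dict[str, float]:
    return {"eGFP": 100.0, "TagRFP": 100.0, "LysoTracker": 80.0}


@dataclass
class SyntheticImageSpec:
    """Parameters of one synthetic field.

    Defaults describe a segmentation-grade flux field: a few large cells
    (hard-disc area comfortably above the 5000-px small-component
    cutoff) whose centers keep ``min_center_spacing`` so ground-truth
    masks are disjoint and recoverable. ``channel_intensity`` maps each
    synthesized channel role to the per-cell base intensity (arbitrary
    fluorescence units). Debris discs are capped at radius 35 px so
    their area stays below the cutoff.
    """

    height: int = 640
    width: int = 640
    n_cells: int = 5
    cell_radius_range: tuple[float, float] = (42.0, 52.0)
    channel_intensity: dict[str, float] = dc_field(default_factory=_default_flux_channels)
    background_level: float = 10.0
    noise_sd: float = 20.0
    n_debris: int = 2
    debris_radius_range: tuple[float, float] = (15.0, 35.0)
    dead_fraction: float = 0.0
    min_center_spacing: float = 120.0
    pi_threshold: float = 50.0
    segmentation_grade: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must lie in [0, 1]")
        rmin, rmax = self.cell_radius_range
        if rmin > rmax or rmin <= 0:
            raise ValueError("invalid cell_radius_range")
        if self.segmentation_grade and math.pi * rmin**2 < SMALL_COMPONENT_AREA:
            raise ValueError(
                "segmentation-grade spec requires hard-disc area >= "
                f"{SMALL_COMPONENT_AREA} px (radius >= "
                f"{math.sqrt(SMALL_COMPONENT_AREA / math.pi):.1f})"
            )
        dmax = self.debris_radius_range[1]
        if math.pi * dmax**2 >= SMALL_COMPONENT_AREA:
            raise ValueError("debris discs must stay below the small-component area")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def viability_defaults(cls, **overrides) -> "SyntheticImageSpec":
        """Spec for a nuclei-counting field: many small Hoechst blobs,
        PI signal on the dead subset, spacing at least twice the
        detector's 10-px minimum distance."""
        params = dict(
            height=512,
            width=512,
            n_cells=50,
            cell_radius_range=(7.0, 10.0),
            channel_intensity={"Hoechst": 100.0, "PI": 120.0},
            background_level=10.0,
            noise_sd=20.0,
            n_debris=0,
            dead_fraction=0.1,
            min_center_spacing=25.0,
            segmentation_grade=False,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class SyntheticImageTruth:
    """Ground truth for one synthetic field.

    ``labels`` is a label grid: 0 background, ``i + 1`` marks the hard
    disc of cell ``i`` (the cosine taper lies outside the truth mask, so
    within-mask intensity is exactly the recorded per-cell mean).
    Debris is not part of the truth foreground.
    """

    centers: np.ndarray  # (n_cells, 2) float, (row, col)
    radii: np.ndarray  # (n_cells,)
    labels: np.ndarray  # int grid, 0 = background
    channel_means: pd.DataFrame  # n_cells x roles
    live: np.ndarray  # (n_cells,) bool

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def mask(self, i: int) -> np.ndarray:
        return self.labels == i + 1

    @property
    def union_mask(self) -> np.ndarray:
        return self.labels > 0


def _disc_profile(height: int, width: int, center: tuple[float, float], radius: float
                  ) -> tuple[slice, slice, np.ndarray]:
    """Return a local window and the tapered radial profile inside it."""
    r0, c0 = center
    reach = int(math.ceil(radius + EDGE_TAPER_PX)) + 1
    rs = slice(max(0, int(r0) - reach), min(height, int(r0) + reach + 1))
    cs = slice(max(0, int(c0) - reach), min(width, int(c0) + reach + 1))
    rr, cc = np.mgrid[rs, cs]
    d = np.hypot(rr - r0, cc - c0)
    prof = np.zeros_like(d)
    prof[d <= radius] = 1.0
    edge = (d > radius) & (d <= radius + EDGE_TAPER_PX)
    prof[edge] = 0.5 * (1.0 + np.cos(math.pi * (d[edge] - radius) / EDGE_TAPER_PX))
    return rs, cs, prof


def _place_centers(rng: np.random.Generator, spec: SyntheticImageSpec,
                   radii: np.ndarray, debris_radii: np.ndarray) -> np.ndarray:
    """Rejection-sample cell then debris centers.

    Cells keep ``min_center_spacing`` pairwise; debris keeps clear of
    every earlier object by the sum of tapered radii plus a margin, so
    truth masks never merge with debris. Bounded retries, then
    :class:`PlacementError`.
    """
    max_tries = 2000
    placed: list[tuple[float, float, float]] = []  # row, col, exclusion radius
    out = []
    all_radii = list(radii) + list(debris_radii)
    for k, r in enumerate(all_radii):
        is_cell = k < len(radii)
        margin = r + EDGE_TAPER_PX + 1
        lo_r, hi_r = margin, spec.height - margin
        lo_c, hi_c = margin, spec.width - margin
        if lo_r >= hi_r or lo_c >= hi_c:
            raise PlacementError("object radius exceeds field size")
        for _ in range(max_tries):
            pr = rng.uniform(lo_r, hi_r)
            pc = rng.uniform(lo_c, hi_c)
            ok = True
            for qr, qc, qe in placed:
                need = spec.min_center_spacing if is_cell and qe < 0 else (
                    r + abs(qe) + 2 * EDGE_TAPER_PX + 2)
                if is_cell and qe < 0:
                    need = max(need, spec.min_center_spacing)
                if math.hypot(pr - qr, pc - qc) < need:
                    ok = False
                    break
            if ok:
                # cells are tagged with negative exclusion radius so later
                # cells use center spacing, debris uses radius sums
                placed.append((pr, pc, -r if is_cell else r))
                out.append((pr, pc))
                break
        else:
            raise PlacementError(
                f"could not place object {k} after {max_tries} tries under "
                f"spacing {spec.min_center_spacing}"
            )
    return np.asarray(out, dtype=float)


def _render_field(spec: SyntheticImageSpec, roles: tuple[str, ...],
                  rng: np.random.Generator, dead: np.ndarray
                  ) -> tuple[FieldImage, SyntheticImageTruth]:
    radii = rng.uniform(*spec.cell_radius_range, size=spec.n_cells)
    debris_radii = rng.uniform(*spec.debris_radius_range, size=spec.n_debris)
    if spec.n_cells + spec.n_debris:
        centers = _place_centers(rng, spec, radii, debris_radii)
    else:
        centers = np.empty((0, 2))
    cell_centers, debris_centers = centers[: spec.n_cells], centers[spec.n_cells:]

    grids = {role: np.full((spec.height, spec.width), spec.background_level, float)
             for role in roles}
    labels = np.zeros((spec.height, spec.width), dtype=np.int32)
    means = np.zeros((spec.n_cells, len(roles)))

    for i in range(spec.n_cells):
        rs, cs, prof = _disc_profile(spec.height, spec.width,
                                     tuple(cell_centers[i]), radii[i])
        labels[rs, cs][prof >= 1.0] = i + 1
        for j, role in enumerate(roles):
            base = spec.channel_intensity.get(role, 0.0)
            if role == "PI":
                base = base if dead[i] else 0.0
            grids[role][rs, cs] += base * prof
            means[i, j] = base

    # debris carries the cytoplasmic-channel signal only, so it crosses the
    # intensity threshold and must be removed by the area rule
    for k in range(spec.n_debris):
        rs, cs, prof = _disc_profile(spec.height, spec.width,
                                     tuple(debris_centers[k]), debris_radii[k])
        for role in roles:
            if role in ("Hoechst", "PI"):
                continue
            grids[role][rs, cs] += spec.channel_intensity.get(role, 0.0) * prof

    if spec.noise_sd > 0:
        for role in roles:
            grids[role] += rng.normal(0.0, spec.noise_sd, size=grids[role].shape)
            np.clip(grids[role], 0.0, None, out=grids[role])

    field = FieldImage(channels={r: grids[r] for r in roles},
                       field_id=f"synthetic-{spec.seed}")
    truth = SyntheticImageTruth(
        centers=cell_centers,
        radii=radii,
        labels=labels,
        channel_means=pd.DataFrame(means, columns=list(roles)),
        live=~dead,
    )
    return field, truth


def generate_flux_field(spec: SyntheticImageSpec
                        ) -> tuple[FieldImage, SyntheticImageTruth]:
    """Synthesize a tandem-sensor flux field (eGFP + TagRFP at least)."""
    roles = tuple(spec.channel_intensity)
    for needed in ("eGFP", "TagRFP"):
        if needed not in roles:
            raise ValueError(f"flux field spec must include channel {needed!r}")
    rng = np.random.default_rng(spec.seed)
    dead = np.zeros(spec.n_cells, dtype=bool)
    return _render_field(spec, roles, rng, dead)


def generate_viability_field(spec: SyntheticImageSpec
                             ) -> tuple[FieldImage, SyntheticImageTruth]:
    """Synthesize a Hoechst/PI viability field.

    Every cell emits a Hoechst blob; exactly ``round(dead_fraction *
    n_cells)`` cells also emit PI signal above ``spec.pi_threshold``.
    """
    roles = tuple(spec.channel_intensity)
    for needed in ("Hoechst", "PI"):
        if needed not in roles:
            raise ValueError(f"viability field spec must include channel {needed!r}")
    if spec.channel_intensity["PI"] <= spec.pi_threshold:
        raise ValueError("PI base intensity must exceed pi_threshold")
    rng = np.random.default_rng(spec.seed)
    n_dead = round(spec.dead_fraction * spec.n_cells)
    dead = np.zeros(spec.n_cells, dtype=bool)
    if n_dead:
        dead[rng.choice(spec.n_cells, size=n_dead, replace=False)] = True
    return _render_field(spec, roles, rng, dead)


# ---------------------------------------------------------------------------
# proteomics side
# ---------------------------------------------------------------------------

@dataclass
class SyntheticProteomeSpec:
    """Parameters of a synthetic label-free abundance matrix.

    Per-protein true variances follow scaled-inv-chi-square(``prior_df``,
    ``prior_var``); replicate log2 intensities are Normal around the
    protein baseline plus the condition effect. A ``de_fraction`` of
    proteins receives a +/- ``effect_size`` log2 shift in every
    non-control condition. Entries then go missing with probability
    ``logistic(-missing_steepness * (value - missing_midpoint))`` so
    missingness concentrates at low abundance; ``missing_midpoint=None``
    disables missingness. Defaults emulate MaxLFQ-style log2 intensities
    (baseline ~ N(25, 2)) with a per-protein noise sd around 0.25.
    """

    n_proteins: int = 2000
    n_conditions: int = 2
    n_replicates: int = 3
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    prior_df: float = 4.0
    prior_var: float = 0.0625
    de_fraction: float = 0.1
    effect_size: float = 1.0
    missing_steepness: float = 1.5
    missing_midpoint: float | None = 20.0
    peptide_rate: float = 2.5
    control: str = "CTR"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.prior_df <= 0 or self.prior_var <= 0:
            raise ValueError("variance prior parameters must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.n_conditions < 2:
            raise ValueError("need a control plus at least one treatment")

    @property
    def condition_names(self) -> list[str]:
        return [self.control] + [f"T{i}" for i in range(1, self.n_conditions)]


@dataclass
class SyntheticProteomeTruth:
    variance: np.ndarray  # true per-protein sigma^2_g, log2^2 units
    is_de: np.ndarray  # bool per protein
    log2fc: np.ndarray  # signed true effect, 0 for non-DE
    missing: pd.DataFrame  # bool grid proteins x samples
    log2_values: pd.DataFrame  # complete (pre-missingness) log2 matrix


def generate_abundance_matrix(spec: SyntheticProteomeSpec):
    """Generate an (AbundanceMatrix, SyntheticProteomeTruth) pair.

    The returned matrix is on the raw intensity scale (``2 ** log2``)
    with missing entries as NaN, mimicking a MaxLFQ report ready for
    log2 normalization.
    """
    from .proteomics import AbundanceMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    n, k, r = spec.n_proteins, spec.n_conditions, spec.n_replicates
    conditions = spec.condition_names
    samples = [f"{c}_{i + 1}" for c in conditions for i in range(r)]
    design = pd.Series({s: s.rsplit("_", 1)[0] for s in samples}, name="condition")

    # scaled inverse-chi-square draws: d0 * s0^2 / chi2_d0
    variance = spec.prior_df * spec.prior_var / rng.chisquare(spec.prior_df, size=n)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n)

    n_de = round(spec.de_fraction * n)
    is_de = np.zeros(n, dtype=bool)
    log2fc = np.zeros(n)
    if n_de:
        idx = rng.choice(n, size=n_de, replace=False)
        is_de[idx] = True
        log2fc[idx] = spec.effect_size * rng.choice([-1.0, 1.0], size=n_de)

    effect = np.zeros((n, k * r))
    for j, c in enumerate(conditions):
        if c == spec.control:
            continue
        effect[:, j * r:(j + 1) * r] = log2fc[:, None]

    values = (baseline[:, None] + effect
              + rng.normal(size=(n, k * r)) * np.sqrt(variance)[:, None])
    protein_ids = [f"P{i:05d}" for i in range(n)]
    log2_df = pd.DataFrame(values, index=protein_ids, columns=samples)

    if spec.missing_midpoint is None or spec.missing_steepness == 0:
        missing = np.zeros_like(values, dtype=bool)
    else:
        from scipy.special import expit
        p_miss = expit(-spec.missing_steepness * (values - spec.missing_midpoint))
        missing = rng.uniform(size=values.shape) < p_miss

    raw = np.power(2.0, values)
    raw[missing] = np.nan
    intensities = pd.DataFrame(raw, index=protein_ids, columns=samples)
    peptides = pd.Series(1 + rng.poisson(spec.peptide_rate, size=n),
                         index=protein_ids, name="n_proteotypic_peptides")

    matrix = AbundanceMatrix(
        intensities=intensities,
        peptide_counts=peptides,
        design=design,
        control=spec.control,
        scale="raw",
    )
    truth = SyntheticProteomeTruth(
        variance=variance,
        is_de=is_de,
        log2fc=log2fc,
        missing=pd.DataFrame(missing, index=protein_ids, columns=samples),
        log2_values=log2_df,
    )
    return matrix, truth
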