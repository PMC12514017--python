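"""Synthetic-data generators for the whole pipeline.

Every input the analysis consumes can be generated here with the statistical
structure the analysis assumes: a multi-site patient/control cohort with
age-related cortical thinning and a planted sex-by-group atrophy interaction;
spatially autocorrelated regional gene-expression maps with a planted gene
set tracking the interaction map; donor-level microarray bundles with probe
redundancy and background-call structure; gene-set collections; and a
GTEx-like genes x tissues TPM table.

All generators are pure functions of (config, seed): the same arguments
always produce the same tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import GeneSet, GeneSetCollection
from .expression import DonorArray, DonorMicroarrayBundle
from .spatial import angular_distance_matrix
from .tissue import TissueTable


class InvalidConfigError(ValueError):
    """A generator configuration violates its invariants."""


GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: Minimum thickness (mm) enforced when clipping noise draws that would
#: otherwise produce non-physical values.
_MIN_THICKNESS_MM = 0.1


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Design of the synthetic patient/control cohort.

    Defaults mirror a male-predominant patient group with sex-balanced-ish
    controls (49 F / 294 M patients vs 131 F / 213 M controls), nine
    acquisition sites, uniform ages 55-80 y with mild age-related thinning,
    and a planted sex-by-group interaction: patients lose thickness in
    ``atrophy_regions``, males (-0.3 mm) more than females (-0.1 mm).
    """

    n_patients_f: int = 49
    n_patients_m: int = 294
    n_controls_f: int = 131
    n_controls_m: int = 213
    n_regions: int = 499
    n_sites: int = 9
    site_shift: float = 0.05       # mm, additive spacing between sites
    site_scale: float = 1.2        # multiplicative noise-scale of the last site
    age_range: tuple[float, float] = (55.0, 80.0)
    age_slope: float = -0.01       # mm / year (negative = thinning)
    atrophy_regions: frozenset[int] = field(default_factory=lambda: frozenset(range(1, 76)))
    atrophy_male: float = -0.3     # mm, peak patient thinning (male)
    atrophy_female: float = -0.1   # mm, peak patient thinning (female)
    #: severity multipliers ramped linearly across the sorted atrophic
    #: regions, emulating graded regional vulnerability; (1, 1) plants a
    #: uniform effect
    atrophy_gradient: tuple[float, float] = (0.2, 1.0)
    noise_sd: float = 0.1          # mm
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_patients_f, self.n_patients_m,
                  self.n_controls_f, self.n_controls_m,
                  self.n_regions, self.n_sites)
        if any(c <= 0 for c in counts):
            raise InvalidConfigError("all counts must be positive")
        if self.noise_sd <= 0:
            raise InvalidConfigError("noise_sd must be > 0")
        if not set(self.atrophy_regions) <= set(range(1, self.n_regions + 1)):
            raise InvalidConfigError("atrophy_regions must be a subset of 1..n_regions")
        if abs(self.atrophy_female) > abs(self.atrophy_male):
            raise InvalidConfigError(
                "|atrophy_female| must not exceed |atrophy_male| "
                "(the planted selective protection)")
        lo, hi = self.atrophy_gradient
        if not (0 <= lo <= hi):
            raise InvalidConfigError("atrophy_gradient must satisfy 0 <= lo <= hi")
        if self.age_range[1] <= self.age_range[0]:
            raise InvalidConfigError("age_range must be increasing")


@dataclass(frozen=True)
class ExpressionConfig:
    """Design of the synthetic regions x genes expression matrix."""

    n_genes: int = 1000
    smoothing_length: float = 0.3  # angular scale (radians) of spatial smoothness
    planted_set_size: int = 20
    planted_coupling: float = 0.8  # correlation of planted-gene maps with the target map
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.planted_coupling <= 1.0:
            raise InvalidConfigError("planted_coupling must lie in [0, 1]")
        if self.planted_set_size < 5:
            raise InvalidConfigError(
                "planted_set_size must be >= 5 so the planted set survives "
                "the enrichment size filter")
        if self.planted_set_size > self.n_genes:
            raise InvalidConfigError("planted_set_size exceeds n_genes")
        if self.smoothing_length < 0:
            raise InvalidConfigError("smoothing_length must be >= 0")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def generate_geometry(n_regions: int, seed: int) -> pd.DataFrame:
    """Quasi-uniform region centroids of one hemisphere's registration sphere.

    Surface-registration pipelines map each cortical hemisphere onto an
    entire sphere; the spin test rotates that full sphere. Points follow a
    Fibonacci lattice over the whole unit sphere, rotated by a
    seed-dependent azimuth so different seeds give different (still
    quasi-uniform) layouts. MNI stand-in coordinates are the sphere
    coordinates scaled to a 100 mm radius.

    Returns a table with columns region_id, hemisphere, sx, sy, sz (unit
    vector) and mni_x, mni_y, mni_z (mm).
    """
    if n_regions < 10:
        raise InvalidConfigError("n_regions must be >= 10")
    rng = np.random.default_rng(seed)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_regions)
    z = 1.0 - (2.0 * i + 1.0) / n_regions  # strictly inside (-1, 1)
    r = np.sqrt(1.0 - z ** 2)
    phi = phi0 + i * GOLDEN_ANGLE
    xyz = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    geom = pd.DataFrame({
        "region_id": i + 1,
        "hemisphere": "L",
        "sx": xyz[:, 0], "sy": xyz[:, 1], "sz": xyz[:, 2],
        "mni_x": 100 * xyz[:, 0], "mni_y": 100 * xyz[:, 1], "mni_z": 100 * xyz[:, 2],
    })
    return geom


def sphere_coords(geom: pd.DataFrame) -> np.ndarray:
    """(n, 3) unit-sphere centroids in region order."""
    return geom[["sx", "sy", "sz"]].to_numpy(dtype=float)


def mni_coords(geom: pd.DataFrame) -> np.ndarray:
    """(n, 3) MNI centroids (mm) in region order."""
    return geom[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def _atrophy_severity(cfg: CohortConfig, geom: pd.DataFrame) -> np.ndarray:
    """Per-region severity multipliers: a linear ramp over the sorted
    atrophic region ids (graded regional vulnerability), 0 elsewhere."""
    region_ids = geom["region_id"].to_numpy()
    severity = np.zeros(len(region_ids))
    targets = np.array(sorted(cfg.atrophy_regions))
    if targets.size:
        lo, hi = cfg.atrophy_gradient
        ramp = np.linspace(lo, hi, targets.size) if targets.size > 1 else np.array([hi])
        severity[np.searchsorted(region_ids, targets)] = ramp
    return severity


def _regional_baseline(geom: pd.DataFrame) -> np.ndarray:
    # smooth, deterministic regional baseline around 2.5 mm
    xyz = sphere_coords(geom)
    return 2.5 + 0.15 * xyz[:, 2] + 0.10 * xyz[:, 1]


def generate_cohort(cfg: CohortConfig,
                    geom: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Participant table and raw thickness matrix.

    thickness(i, r) = baseline(r) + age_slope * (age_i - mean age)
                      + site_shift(site_i) + site_scale(site_i) * eps(i, r)
                      + atrophy(sex_i) * [i is a patient and r is atrophic]

    Sites are assigned round-robin over the participant order; additive site
    offsets are centered multiples of ``site_shift`` and multiplicative noise
    scales interpolate from 1 to ``site_scale`` across sites.
    """
    cfg.validate()
    if len(geom) != cfg.n_regions:
        raise InvalidConfigError("geometry size does not match n_regions")
    rng = np.random.default_rng(cfg.seed)

    groups = (["patient"] * (cfg.n_patients_f + cfg.n_patients_m)
              + ["control"] * (cfg.n_controls_f + cfg.n_controls_m))
    sexes = (["F"] * cfg.n_patients_f + ["M"] * cfg.n_patients_m
             + ["F"] * cfg.n_controls_f + ["M"] * cfg.n_controls_m)
    n = len(groups)
    ages = rng.uniform(*cfg.age_range, size=n)
    sites = np.arange(n) % cfg.n_sites

    participants = pd.DataFrame({
        "participant_id": [f"sub-{k:04d}" for k in range(1, n + 1)],
        "group": groups,
        "sex": sexes,
        "age": ages,
        "site": [f"site{int(s) + 1:02d}" for s in sites],
    }).set_index("participant_id")

    baseline = _regional_baseline(geom)
    shift = (sites - (cfg.n_sites - 1) / 2.0) * cfg.site_shift
    if cfg.n_sites > 1:
        scale = 1.0 + (cfg.site_scale - 1.0) * sites / (cfg.n_sites - 1)
    else:
        scale = np.ones(n)

    eps = rng.normal(0.0, cfg.noise_sd, size=(n, cfg.n_regions))
    thick = (baseline[None, :]
             + cfg.age_slope * (ages - ages.mean())[:, None]
             + shift[:, None]
             + scale[:, None] * eps)

    severity = _atrophy_severity(cfg, geom)
    is_patient = np.array([g == "patient" for g in groups])
    amp = np.where(np.array(sexes) == "M", cfg.atrophy_male, cfg.atrophy_female)
    thick += np.outer(is_patient * amp, severity)

    if (thick <= 0).any():
        n_bad = int((thick <= 0).sum())
        warnings.warn(
            f"{n_bad} generated thickness values were <= 0 mm; "
            f"noise clipped to keep values >= {_MIN_THICKNESS_MM} mm")
        thick = np.maximum(thick, _MIN_THICKNESS_MM)

    thickness = pd.DataFrame(thick, index=participants.index,
                             columns=geom["region_id"].to_numpy())
    return participants, thickness


def true_interaction_map(cfg: CohortConfig, geom: pd.DataFrame) -> pd.Series:
    """Ground-truth sex-interaction map implied by the cohort config.

    Positive where females are planted to lose less thickness than males:
    severity * (atrophy_female - atrophy_male) on the atrophic regions, 0
    elsewhere, matching the sign convention of the fitted estimates.
    """
    vals = _atrophy_severity(cfg, geom) * (cfg.atrophy_female - cfg.atrophy_male)
    return pd.Series(vals, index=geom["region_id"].to_numpy(), name="interaction")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _smooth_fields(xyz: np.ndarray, n_fields: int, length: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Zero-mean Gaussian random fields with exponential angular covariance."""
    n = xyz.shape[0]
    white = rng.standard_normal((n, n_fields))
    if length <= 1e-12:
        return white
    theta = angular_distance_matrix(xyz)
    cov = np.exp(-theta / length)
    cov[np.diag_indices_from(cov)] += 1e-8
    chol = np.linalg.cholesky(cov)
    return chol @ white


def _zscore_columns(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=0)
    sd = a.std(axis=0)
    sd[sd == 0] = 1.0
    return (a - mu) / sd


def generate_expression(cfg: ExpressionConfig, geom: pd.DataFrame,
                        interaction_map: np.ndarray | pd.Series,
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Regions x genes expression with a planted coupled gene set.

    Background genes are spatially smoothed Gaussian fields; planted genes
    mix the standardized interaction map (weight ``planted_coupling``) with
    independent smoothed noise. Every gene column is standardized to mean 0,
    SD 1 across regions.
    """
    cfg.validate()
    y = np.asarray(interaction_map, dtype=float)
    if y.size != len(geom):
        raise InvalidConfigError("interaction_map length must equal n_regions")
    if y.std() == 0:
        raise InvalidConfigError("interaction_map is constant; nothing to couple to")
    rng = np.random.default_rng(cfg.seed)
    xyz = sphere_coords(geom)

    fields = _zscore_columns(_smooth_fields(xyz, cfg.n_genes, cfg.smoothing_length, rng))
    z_map = (y - y.mean()) / y.std()

    genes = [f"G{k:05d}" for k in range(1, cfg.n_genes + 1)]
    planted_idx = rng.choice(cfg.n_genes, size=cfg.planted_set_size, replace=False)
    c = cfg.planted_coupling
    fields[:, planted_idx] = (c * z_map[:, None]
                              + np.sqrt(1.0 - c ** 2) * fields[:, planted_idx])
    expr = pd.DataFrame(_zscore_columns(fields),
                        index=geom["region_id"].to_numpy(), columns=genes)
    planted = sorted(genes[i] for i in planted_idx)
    return expr, planted


# ---------------------------------------------------------------------------
# donor microarray bundles
# ---------------------------------------------------------------------------

def generate_donor_microarrays(n_donors: int, true_expression: pd.DataFrame,
                               geom: pd.DataFrame, seed: int,
                               region_coverage: float = 0.9,
                               jitter_mm: float = 2.0,
                               n_unassignable: int = 3) -> DonorMicroarrayBundle:
    """Donor-level microarray bundle consistent with a true expression matrix.

    Each donor samples ~``region_coverage`` of the regions (one tissue sample
    per covered region, MNI coordinates jittered around the region centroid)
    plus a few deliberately unassignable far-off samples. Each gene carries
    1-3 probes: one high-fidelity probe tracking the true regional profile,
    and optionally a noisy probe and/or a background-failing probe whose
    above-background call rate is low. Donors differ by a global intensity
    scale, which downstream normalization must remove.
    """
    if n_donors < 2:
        raise InvalidConfigError("n_donors must be >= 2")
    rng = np.random.default_rng(seed)
    genes = list(true_expression.columns)
    region_ids = geom["region_id"].to_numpy()
    mni = mni_coords(geom)

    probe_rows = []
    probe_kind = {}
    pid = 0
    for g in genes:
        n_probes = rng.integers(1, 4)
        kinds = ["hifi"] + rng.choice(["noisy", "failing"], size=n_probes - 1).tolist()
        for kind in kinds:
            pid += 1
            name = f"P{pid:06d}"
            probe_rows.append({"probe_id": name, "gene": g})
            probe_kind[name] = kind
    probes = pd.DataFrame(probe_rows).set_index("probe_id")

    true_z = true_expression.to_numpy()  # regions x genes, z-scored
    gene_pos = {g: i for i, g in enumerate(genes)}
    probe_gene_idx = np.array([gene_pos[g] for g in probes["gene"]])
    donors = {}
    for d in range(1, n_donors + 1):
        covered = rng.random(len(region_ids)) < region_coverage
        cov_idx = np.flatnonzero(covered)
        coords = mni[cov_idx] + rng.normal(0.0, jitter_mm, size=(len(cov_idx), 3))
        src = region_ids[cov_idx].astype(float)
        # far-off samples: well outside the 100 mm hemisphere shell
        far = rng.normal(0.0, 30.0, size=(n_unassignable, 3)) + np.array([250.0, 0.0, 0.0])
        coords = np.vstack([coords, far])
        src = np.concatenate([src, np.full(n_unassignable, np.nan)])
        sample_ids = [f"D{d}S{k:04d}" for k in range(1, len(coords) + 1)]
        samples = pd.DataFrame(coords, index=sample_ids, columns=["mni_x", "mni_y", "mni_z"])
        samples["source_region"] = src

        donor_scale = float(2.0 ** rng.normal(0.0, 0.5))
        n_s = len(sample_ids)
        inten = np.empty((len(probes), n_s))
        bg = np.empty((len(probes), n_s), dtype=bool)
        # per-sample true profile: the source region's expression, or pure
        # noise for the unassignable samples
        safe_src = np.nan_to_num(src, nan=float(region_ids[0])).astype(int)
        prof = true_z[np.searchsorted(region_ids, safe_src)]
        prof = np.where(np.isnan(src)[:, None],
                        rng.standard_normal((n_s, true_z.shape[1])), prof)
        for j, pname in enumerate(probes.index):
            gi = probe_gene_idx[j]
            kind = probe_kind[pname]
            if kind == "hifi":
                signal = prof[:, gi] + rng.normal(0.0, 0.1, n_s)
                p_above = 0.98
            elif kind == "noisy":
                signal = 0.3 * prof[:, gi] + rng.normal(0.0, 1.0, n_s)
                p_above = 0.9
            else:  # failing: near background
                signal = rng.normal(-2.0, 0.3, n_s)
                p_above = 0.35
            inten[j] = donor_scale * 2.0 ** (8.0 + signal)
            bg[j] = rng.random(n_s) < p_above
        donors[f"donor{d}"] = DonorArray(
            intensities=pd.DataFrame(inten, index=probes.index, columns=sample_ids),
            background=pd.DataFrame(bg, index=probes.index, columns=sample_ids),
            samples=samples,
        )
    return DonorMicroarrayBundle(probes=probes, donors=donors)


# ---------------------------------------------------------------------------
# gene sets and tissue table
# ---------------------------------------------------------------------------

PLANTED_SET_NAME = "PLANTED_INTERACTION"


def generate_genesets(genes: list[str], planted_set: list[str],
                      n_random_sets: int, size_range: tuple[int, int],
                      seed: int) -> GeneSetCollection:
    """Random gene-set collection that includes the planted set by name."""
    lo, hi = size_range
    if lo < 1 or hi > len(genes) or lo > hi:
        raise InvalidConfigError("size_range must lie within [1, n_genes]")
    if not set(planted_set) <= set(genes):
        raise InvalidConfigError("planted_set contains unknown genes")
    rng = np.random.default_rng(seed)
    sets = [GeneSet(term_id=PLANTED_SET_NAME, name="planted interaction-coupled genes",
                    genes=tuple(sorted(planted_set)))]
    for k in range(1, n_random_sets + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(GeneSet(term_id=f"RAND{k:04d}",
                            name=f"random set {k}", genes=tuple(sorted(members))))
    return GeneSetCollection(sets)


def generate_tissue_table(genes: list[str], n_tissues: int = 54,
                          n_brain: int = 13,
                          brain_enriched_genes: list[str] | None = None,
                          seed: int = 0,
                          brain_fold: float = 8.0) -> TissueTable:
    """GTEx-like genes x tissues TPM table with brain-enriched genes.

    Baseline TPM is log-normal per gene and tissue; genes listed in
    ``brain_enriched_genes`` have their TPM multiplied by ``brain_fold`` in
    the ``n_brain`` brain tissues.
    """
    if n_brain < 2 or n_tissues - n_brain < 2:
        raise InvalidConfigError("need at least 2 brain and 2 non-brain tissues")
    brain_enriched_genes = brain_enriched_genes or []
    if not set(brain_enriched_genes) <= set(genes):
        raise InvalidConfigError("brain_enriched_genes contains unknown genes")
    rng = np.random.default_rng(seed)
    tissues = ([f"Brain_{k:02d}" for k in range(1, n_brain + 1)]
               + [f"Tissue_{k:02d}" for k in range(1, n_tissues - n_brain + 1)])
    is_brain = pd.Series([t.startswith("Brain_") for t in tissues], index=tissues)
    base = rng.lognormal(mean=2.0, sigma=1.0, size=(len(genes), n_tissues))
    tpm = pd.DataFrame(base, index=list(genes), columns=tissues)
    if brain_enriched_genes:
        tpm.loc[brain_enriched_genes, is_brain[is_brain].index] *= brain_fold
    return TissueTable(tpm=tpm, is_brain=is_brain)
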