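"""Assembly of a regions x genes expression matrix from donor microarrays.

The pipeline mirrors the standard workflow for donor-level brain microarray
data: (1) discard probes that fail to exceed background noise in at least
half of all samples pooled across donors; (2) map each tissue sample to its
nearest region centroid (Euclidean distance in MNI mm), excluding samples
too far from every centroid and samples outside the analyzed hemisphere;
(3) for genes with several probes, keep the probe with the highest
differential stability (mean across donor pairs of the Pearson correlation
between regional mean profiles); (4) drop genes whose selected probe is
inconsistent across donors; (5) normalize expression within each donor
(scaled robust sigmoid across samples), average within regions within
donors, then across donors, and z-score each gene across regions.

Stage order is enforced: each operation records a flag the next one checks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class DonorArray:
    """One donor's microarray: probe x sample intensities and metadata."""

    intensities: pd.DataFrame   # probes x samples
    background: pd.DataFrame    # probes x samples, True = above background
    samples: pd.DataFrame       # sample metadata: mni_x/y/z (+ region after assignment)


@dataclass
class DonorMicroarrayBundle:
    """Donor microarrays sharing one probe -> gene annotation."""

    probes: pd.DataFrame        # indexed by probe_id, column "gene"
    donors: dict[str, DonorArray]
    background_filtered: bool = False
    samples_assigned: bool = False
    probes_selected: bool = False
    genes_filtered: bool = False
    report: dict = field(default_factory=dict)

    @property
    def donor_ids(self) -> list[str]:
        return list(self.donors)

    def probe_ids(self) -> list[str]:
        return list(self.probes.index)


def _subset_probes(bundle: DonorMicroarrayBundle, keep: pd.Index) -> DonorMicroarrayBundle:
    donors = {
        d: DonorArray(intensities=a.intensities.loc[keep],
                      background=a.background.loc[keep],
                      samples=a.samples)
        for d, a in bundle.donors.items()
    }
    return replace(bundle, probes=bundle.probes.loc[keep], donors=donors)


def filter_probes_background(bundle: DonorMicroarrayBundle,
                             min_fraction: float = 0.5) -> DonorMicroarrayBundle:
    """Keep probes above background in >= min_fraction of pooled samples.

    The fraction pools samples across all donors; the boundary is inclusive
    (a probe at exactly the threshold is kept).
    """
    flags = pd.concat([a.background for a in bundle.donors.values()], axis=1)
    frac = flags.mean(axis=1)
    keep = frac.index[frac >= min_fraction]
    out = _subset_probes(bundle, keep)
    out.background_filtered = True
    out.report = {**bundle.report,
                  "probes_in": len(bundle.probes),
                  "probes_after_background": len(keep)}
    logger.info("background filter: %d -> %d probes", len(bundle.probes), len(keep))
    return out


def assign_samples_to_parcels(bundle: DonorMicroarrayBundle, geom: pd.DataFrame,
                              max_distance_mm: float | None = None,
                              ) -> DonorMicroarrayBundle:
    """Assign each sample to the nearest region centroid within a tolerance.

    Distance is Euclidean in MNI mm. The default tolerance is twice the
    median nearest-centroid spacing of the geometry. Samples beyond the
    tolerance, and samples on the opposite hemisphere (positive x for a
    left-hemisphere geometry), are excluded.
    """
    cent = geom[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
    region_ids = geom["region_id"].to_numpy()
    if max_distance_mm is None:
        d = np.linalg.norm(cent[:, None, :] - cent[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        max_distance_mm = 2.0 * float(np.median(d.min(axis=1)))
    # opposite-hemisphere exclusion only applies when the geometry itself is
    # spatially restricted to one side (x <= 0 for a left-hemisphere atlas)
    left = bool((geom["hemisphere"] == "L").all() and (geom["mni_x"] <= 0).all())

    donors = {}
    n_in = n_kept = 0
    for did, a in bundle.donors.items():
        xyz = a.samples[["mni_x", "mni_y", "mni_z"]].to_numpy(dtype=float)
        dist = np.linalg.norm(xyz[:, None, :] - cent[None, :, :], axis=2)
        nearest = dist.argmin(axis=1)
        ok = dist[np.arange(len(xyz)), nearest] <= max_distance_mm
        if left:
            ok &= xyz[:, 0] <= 0
        samples = a.samples.loc[ok].copy()
        samples["region"] = region_ids[nearest[ok]]
        donors[did] = DonorArray(intensities=a.intensities.loc[:, ok],
                                 background=a.background.loc[:, ok],
                                 samples=samples)
        n_in += len(a.samples)
        n_kept += int(ok.sum())
    out = replace(bundle, donors=donors)
    out.background_filtered = bundle.background_filtered
    out.samples_assigned = True
    out.report = {**bundle.report, "samples_in": n_in, "samples_assigned": n_kept,
                  "max_distance_mm": float(max_distance_mm)}
    logger.info("sample assignment: %d -> %d samples (tolerance %.1f mm)",
                n_in, n_kept, max_distance_mm)
    return out


def _regional_profiles(bundle: DonorMicroarrayBundle) -> dict[str, pd.DataFrame]:
    """Per donor: probes x regions matrix of mean log2 intensity."""
    out = {}
    for did, a in bundle.donors.items():
        logi = np.log2(a.intensities)
        logi.columns = a.samples["region"].to_numpy()
        out[did] = logi.T.groupby(level=0).mean().T
    return out


def _differential_stability(profiles: dict[str, pd.DataFrame],
                            index: pd.Index) -> pd.Series:
    """Mean across-donor-pair Pearson r of regional profiles, per row.

    Pairs sharing fewer than 3 regions are skipped; rows with no valid pair
    get NaN.
    """
    donor_ids = list(profiles)
    sums = pd.Series(0.0, index=index)
    counts = pd.Series(0, index=index)
    for d1, d2 in itertools.combinations(donor_ids, 2):
        p1, p2 = profiles[d1], profiles[d2]
        shared = p1.columns.intersection(p2.columns)
        if len(shared) < 3:
            continue
        a = p1[shared].to_numpy(dtype=float)
        b = p2[shared].to_numpy(dtype=float)
        a = a - a.mean(axis=1, keepdims=True)
        b = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (a * b).sum(axis=1) / denom
        valid = np.isfinite(r)
        sums[valid] += r[valid]
        counts[valid] += 1
    ds = sums / counts.replace(0, np.nan)
    return ds.rename("differential_stability")


def select_probe_per_gene(bundle: DonorMicroarrayBundle) -> DonorMicroarrayBundle:
    """Keep, per gene, the probe with maximal differential stability.

    Ties (including genes whose stability is undefined) resolve to the
    lowest probe id. Requires samples to be assigned first.
    """
    if not bundle.samples_assigned:
        raise RuntimeError("assign_samples_to_parcels must run before probe selection")
    ds = _differential_stability(_regional_profiles(bundle), bundle.probes.index)
    tab = bundle.probes.copy()
    tab["ds"] = ds
    # sort: gene, then DS descending (NaN last), then probe id ascending
    tab = tab.sort_values(["gene", "ds"], ascending=[True, False],
                          kind="mergesort", na_position="last")
    keep = tab.groupby("gene", sort=True).head(1).index.sort_values()
    dropped_genes = 0  # genes vanish only if all probes were background-filtered
    out = _subset_probes(bundle, keep)
    out.background_filtered = bundle.background_filtered
    out.samples_assigned = bundle.samples_assigned
    out.probes_selected = True
    out.report = {**bundle.report, "genes_after_probe_selection": len(keep),
                  "genes_dropped_no_probe": dropped_genes}
    return out


def filter_inconsistent_genes(bundle: DonorMicroarrayBundle,
                              min_stability: float = 0.1) -> DonorMicroarrayBundle:
    """Drop genes whose across-donor differential stability < min_stability."""
    if not bundle.probes_selected:
        raise RuntimeError("select_probe_per_gene must run before gene filtering")
    if min_stability <= 0:
        keep = bundle.probes.index
    else:
        if len(bundle.donors) < 2:
            raise ValueError("differential stability needs >= 2 donors")
        ds = _differential_stability(_regional_profiles(bundle), bundle.probes.index)
        keep = ds.index[ds.fillna(-np.inf) >= min_stability]
    out = _subset_probes(bundle, keep)
    out.background_filtered = bundle.background_filtered
    out.samples_assigned = bundle.samples_assigned
    out.probes_selected = bundle.probes_selected
    out.genes_filtered = True
    out.report = {**bundle.report, "genes_after_consistency": len(keep),
                  "min_stability": min_stability}
    logger.info("consistency filter: %d -> %d genes", len(bundle.probes), len(keep))
    return out


def _scaled_robust_sigmoid(x: np.ndarray) -> np.ndarray:
    """Row-wise scaled robust sigmoid, rescaled to [0, 1].

    u = 1 / (1 + exp(-(x - median) / (IQR / 1.35))); rows with zero IQR map
    to a constant 0.5.
    """
    med = np.median(x, axis=1, keepdims=True)
    q75, q25 = np.percentile(x, [75, 25], axis=1)
    iqr = (q75 - q25)[:, None]
    scale = iqr / 1.35
    with np.errstate(over="ignore"):
        u = np.where(scale > 0, 1.0 / (1.0 + np.exp(-(x - med) / np.where(scale > 0, scale, 1.0))), 0.5)
    lo = u.min(axis=1, keepdims=True)
    hi = u.max(axis=1, keepdims=True)
    rng = hi - lo
    return np.where(rng > 0, (u - lo) / np.where(rng > 0, rng, 1.0), 0.5)


def normalize_and_aggregate(bundle: DonorMicroarrayBundle,
                            method: str = "srs") -> pd.DataFrame:
    """Regions x genes matrix: normalize per donor, average, z-score.

    Per donor, each gene's log2 intensities are normalized across that
    donor's samples (``method='srs'`` scaled robust sigmoid, the default;
    ``method='zscore'`` plain standardization, useful when a strictly linear
    normalization is wanted), averaged over samples within each region, and
    then averaged across donors per region. Gene values are finally z-scored
    across the retained regions. Regions with no samples in any donor are
    dropped with a log message.
    """
    if not (bundle.background_filtered and bundle.samples_assigned
            and bundle.probes_selected and bundle.genes_filtered):
        raise RuntimeError(
            "pipeline order is background filter -> sample assignment -> "
            "probe selection -> gene consistency filter -> normalize/aggregate")
    genes = bundle.probes["gene"]
    per_donor = []
    for did, a in bundle.donors.items():
        x = np.log2(a.intensities.to_numpy(dtype=float))
        if method == "srs":
            norm = _scaled_robust_sigmoid(x)
        elif method == "zscore":
            mu = x.mean(axis=1, keepdims=True)
            sd = x.std(axis=1, keepdims=True)
            norm = (x - mu) / np.where(sd > 0, sd, 1.0)
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        df = pd.DataFrame(norm, index=genes.to_numpy(),
                          columns=a.samples["region"].to_numpy())
        per_donor.append(df.T.groupby(level=0).mean())  # regions x genes
    stacked = pd.concat(per_donor, keys=bundle.donor_ids)
    regional = stacked.groupby(level=1).mean()  # mean over donors per region
    regional.index.name = "region_id"
    regional = regional.sort_index()
    regional = regional.loc[:, sorted(regional.columns)]
    mu = regional.mean(axis=0)
    sd = regional.std(axis=0, ddof=0)
    z = (regional - mu) / sd.replace(0, 1.0)
    if z.isna().any().any():
        raise ValueError("assembled expression matrix contains missing values")
    return z
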