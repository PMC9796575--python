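"""Per-OTU correlation screening against environmental factors.

The screening procedure asks, for each site, which OTUs track each of six
environmental factors (sediment depth, volumetric water content, total
interstitial space, gas space, particle size, particle evenness):

1. Spearman correlation of every OTU's relative abundance with the factor
   across the site's depth-ordered layers (tie-corrected; the p-value is an
   exact two-sided permutation probability for small layer counts).
2. OTUs with p > 0.05 are removed; Benjamini–Hochberg q-values are computed
   over the (site, factor) family and entries with q >= 0.05 are flagged.
3. |rho| values are ranked and the cumulative relative abundance of
   correlated OTUs is traced as a function of the |rho| threshold.
4. A pseudo-correlation diagnostic compares a factor's correlated-OTU set
   with sediment depth's: a factor that is itself strongly collinear with
   depth and whose correlated OTUs are largely a subset of depth's is
   flagged as a likely pseudo-correlation (it mirrors the gradient rather
   than driving the community).

With only 7–9 layers per site the large-sample t approximation for the
Spearman p-value is unreliable, so for n <= 9 the p-value is computed by
full enumeration of the n! rank permutations (tie patterns handled by
grouping OTUs with the same mid-rank multiset, whose null distributions
coincide).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .otu import RelAbundanceTable, phylum_of

__all__ = [
    "FACTORS",
    "EnvMatrix",
    "SpearmanResult",
    "ScreenEntry",
    "ThresholdCurve",
    "PseudoDiagnostic",
    "spearman",
    "bh_fdr",
    "screen_site",
    "screen_all",
    "threshold_curve",
    "correlated_abundance_at",
    "phylum_composition",
    "pseudo_correlation_diagnostic",
]

#: the six screened environmental factors
FACTORS = ("depth", "vwc", "tis", "gas_space", "p_size", "p_evenness")

#: largest n for which the exact permutation null is enumerated (9! = 362,880)
MAX_EXACT_N = 9


@dataclass
class EnvMatrix:
    """Per-site environmental factor profiles.

    ``sites`` maps site id to a DataFrame indexed by strictly increasing
    layer depth (cm) with one column per factor (``depth`` itself included
    as a column so it screens like any other factor).  Missing cells are
    allowed; correlations use pairwise-complete observations.
    """

    sites: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for site, df in self.sites.items():
            depths = np.asarray(df.index, dtype=float)
            if not np.all(np.diff(depths) > 0):
                raise ValueError(f"depths not strictly increasing at {site}")

    @classmethod
    def from_layer_table(cls, long_df: pd.DataFrame) -> "EnvMatrix":
        """Build from a long-format physics table (site_id, depth_cm,
        variable, value)."""
        sites = {}
        for site, grp in long_df.groupby("site_id"):
            wide = grp.pivot_table(
                index="depth_cm", columns="variable", values="value", dropna=False
            ).sort_index()
            wide.insert(0, "depth", wide.index.to_numpy(dtype=float))
            sites[site] = wide
        return cls(sites=sites)

    def factor(self, site: str, name: str) -> pd.Series:
        df = self.sites[site]
        if name not in df.columns:
            raise KeyError(f"factor {name!r} not measured at {site}")
        return df[name]


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int
    method: str
    reason: str | None = None

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.rho)


@dataclass(frozen=True)
class ScreenEntry:
    """One OTU's screening record for a (site, factor) pair."""

    site_id: str
    factor: str
    otu_id: str
    rho: float
    p_value: float
    q_value: float
    mean_ra: float
    fdr_pass: bool

    @property
    def abs_rho(self) -> float:
        return abs(self.rho)


# ---------------------------------------------------------------------------
# exact permutation machinery

_PERM_IDX: dict[int, np.ndarray] = {}


def _perm_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) index array (cached)."""
    if n not in _PERM_IDX:
        _PERM_IDX[n] = np.array(
            list(itertools.permutations(range(n))), dtype=np.int8
        )
    return _PERM_IDX[n]


def _midrank(a: np.ndarray, axis: int = -1) -> np.ndarray:
    return stats.rankdata(a, axis=axis)


def _bulk_spearman(x: np.ndarray, Y: np.ndarray, method: str = "auto"):
    """Spearman rho and two-sided p of ``x`` against every row of ``Y``.

    ``method``: "exact" enumerates all n! permutations (n <= 9 only),
    "approx" uses the t approximation, "auto" picks exact for n <= 9.
    Returns ``(rho, p, used_method)``; rho/p are NaN for constant rows.
    """
    x = np.asarray(x, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if method == "auto":
        method = "exact" if n <= MAX_EXACT_N else "approx"
    if method == "exact" and n > MAX_EXACT_N:
        raise ValueError(f"exact enumeration limited to n <= {MAX_EXACT_N}")

    xr = _midrank(x)
    Yr = _midrank(Y, axis=1)
    xc = xr - xr.mean()
    Yc = Yr - Yr.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((Yc**2).sum(axis=1))
    valid = (sx > 0) & (sy > 0)
    S = Yc @ xc
    rho = np.full(Y.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho[valid] = np.clip(S[valid] / (sx * sy[valid]), -1.0, 1.0)

    p = np.full(Y.shape[0], np.nan)
    if method == "approx":
        r = rho[valid]
        with np.errstate(invalid="ignore", divide="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
        p[valid] = np.clip(2 * stats.t.sf(np.abs(t), df=n - 2), 0.0, 1.0)
        return rho, p, method

    perm = _perm_indices(n)
    Pc = xc[perm]  # (n!, n) permuted centered x mid-ranks
    nfact = perm.shape[0]
    # group rows by tie pattern: the permutation null of the cross-product
    # depends only on the multiset of y mid-ranks
    patterns: dict[tuple, np.ndarray] = {}
    for i in np.nonzero(valid)[0]:
        key = tuple(np.sort(Yr[i]))
        patterns.setdefault(key, []).append(i)
    for key, rows in patterns.items():
        y0 = np.asarray(key, dtype=float)
        y0c = y0 - y0.mean()
        null_T = np.sort(np.abs(Pc @ y0c))
        eps = 1e-9 * sx * np.sqrt((y0c**2).sum())
        obs = np.abs(S[rows])
        ge = nfact - np.searchsorted(null_T, obs - eps, side="left")
        p[rows] = ge / nfact
    return rho, p, method


def spearman(x, y, method: str = "auto") -> SpearmanResult:
    """Tie-corrected Spearman correlation with exact small-n p-value.

    Missing values are removed pairwise; fewer than 3 complete pairs or a
    constant vector yields a missing result with a reason rather than an
    exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return SpearmanResult(np.nan, np.nan, n, "none", "fewer than 3 complete pairs")
    xv, yv = x[mask], y[mask]
    if np.unique(xv).size < 2 or np.unique(yv).size < 2:
        return SpearmanResult(np.nan, np.nan, n, "none", "constant input")
    rho, p, used = _bulk_spearman(xv, yv[None, :], method=method)
    return SpearmanResult(float(rho[0]), float(p[0]), n, used)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# site-level screening


def screen_site(
    ra_site: RelAbundanceTable,
    env: EnvMatrix | pd.DataFrame,
    factor: str,
    *,
    site_id: str | None = None,
    p_gate: float = 0.05,
    fdr_alpha: float = 0.05,
    method: str = "auto",
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Screen every OTU of one site against one environmental factor.

    ``ra_site`` must hold a single site's samples; they are ordered by depth
    and aligned to the environmental profile by depth value.  Returns a
    DataFrame (one row per retained OTU) with columns ``rho``, ``p_value``,
    ``q_value``, ``abs_rho``, ``mean_ra``, ``fdr_pass``, sorted by
    decreasing |rho|.  OTUs with undefined correlation (constant abundance)
    are excluded; those with p > ``p_gate`` are removed; q-values are
    Benjamini–Hochberg over all tested OTUs of this (site, factor) family.
    """
    sites = ra_site.sample_meta["site_id"].unique()
    if len(sites) != 1:
        raise ValueError(f"expected one site, got {list(sites)}")
    site = site_id or str(sites[0])
    env_df = env.sites[site] if isinstance(env, EnvMatrix) else env
    if factor not in env_df.columns:
        raise KeyError(f"factor {factor!r} absent from environmental matrix")

    meta = ra_site.sample_meta.sort_values("depth_cm")
    depths = meta["depth_cm"].to_numpy(dtype=float)
    env_depths = env_df.index.to_numpy(dtype=float)
    unmatched = [d for d in depths if not np.any(np.isclose(env_depths, d))]
    if unmatched:
        raise ValueError(
            f"sample depths without environmental rows at {site}: {unmatched}"
        )
    idx = [int(np.argmin(np.abs(env_depths - d))) for d in depths]
    x = env_df[factor].to_numpy(dtype=float)[idx]

    props = ra_site.proportions.loc[meta.index]
    mean_ra = props.mean(axis=0)  # over all of the site's layers

    mask = np.isfinite(x)
    n_eff = int(mask.sum())
    if n_eff < min_pairs or np.unique(x[mask]).size < 2:
        warnings.warn(
            f"factor {factor!r} skipped at {site}: "
            f"{n_eff} complete pairs (< {min_pairs}) or constant profile",
            stacklevel=2,
        )
        out = pd.DataFrame(
            columns=["rho", "p_value", "q_value", "abs_rho", "mean_ra", "fdr_pass"]
        )
        out.attrs.update(site=site, factor=factor, n_layers=n_eff, skipped=True)
        return out

    Y = props.values.T[:, mask]  # OTUs x complete layers
    rho, p, used = _bulk_spearman(x[mask], Y, method=method)

    valid = np.isfinite(p)
    q = np.full_like(p, np.nan)
    q[valid] = bh_fdr(p[valid])

    out = pd.DataFrame(
        {
            "rho": rho,
            "p_value": p,
            "q_value": q,
            "abs_rho": np.abs(rho),
            "mean_ra": mean_ra.values,
            "fdr_pass": q < fdr_alpha,
        },
        index=pd.Index(props.columns, name="otu_id"),
    )
    out = out[valid & (out["p_value"] <= p_gate)]
    out = out.sort_values("abs_rho", ascending=False)
    out.attrs.update(
        site=site,
        factor=factor,
        n_layers=n_eff,
        n_tested=int(valid.sum()),
        p_method=used,
        p_gate=p_gate,
        fdr_alpha=fdr_alpha,
        skipped=False,
    )
    return out


def screen_all(
    ra: RelAbundanceTable,
    env: EnvMatrix,
    factors=FACTORS,
    **kwargs,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Run :func:`screen_site` for every site and factor; returns a dict
    keyed by ``(site_id, factor)``."""
    results = {}
    for site in env.sites:
        ra_site = ra.site(site)
        for fac in factors:
            if fac not in env.sites[site].columns:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results[(site, fac)] = screen_site(
                    ra_site, env, fac, site_id=site, **kwargs
                )
    return results


# ---------------------------------------------------------------------------
# threshold curves and composition


@dataclass
class ThresholdCurve:
    """Cumulative correlated abundance versus |rho| threshold.

    ``yra[t]`` sums the mean relative abundance of retained OTUs whose
    |rho| >= t; it is non-increasing in t.  ``points`` carries the
    (|rho|, p) scatter of the retained entries.
    """

    thresholds: np.ndarray
    yra: np.ndarray
    points: pd.DataFrame = field(default_factory=pd.DataFrame)

    def at(self, t: float) -> float:
        i = int(np.argmin(np.abs(self.thresholds - t)))
        return float(self.yra[i])


def _passing(entries: pd.DataFrame, fdr_only: bool) -> pd.DataFrame:
    if fdr_only and "fdr_pass" in entries.columns and len(entries):
        return entries[entries["fdr_pass"].astype(bool)]
    return entries


def threshold_curve(
    entries: pd.DataFrame, step: float = 0.01, fdr_only: bool = True
) -> ThresholdCurve:
    """Trace summed mean_ra of entries with |rho| >= t over a t grid."""
    grid = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    kept = _passing(entries, fdr_only)
    if kept.empty:
        return ThresholdCurve(grid, np.zeros_like(grid), pd.DataFrame())
    abs_rho = kept["abs_rho"].to_numpy()
    mean_ra = kept["mean_ra"].to_numpy()
    order = np.argsort(abs_rho)
    cum = np.concatenate([[0.0], np.cumsum(mean_ra[order][::-1])])[::-1]
    # yra(t) = total abundance of entries with abs_rho >= t
    pos = np.searchsorted(abs_rho[order], grid - 1e-12, side="left")
    yra = cum[pos]
    points = kept[["abs_rho", "p_value"]].reset_index()
    return ThresholdCurve(grid, yra, points)


def correlated_abundance_at(
    entries: pd.DataFrame, t: float = 0.8, fdr_only: bool = True
) -> float:
    """Summed mean relative abundance of OTUs with |rho| strictly > t."""
    kept = _passing(entries, fdr_only)
    if kept.empty:
        return 0.0
    return float(kept.loc[kept["abs_rho"] > t, "mean_ra"].sum())


def correlated_otus(
    entries: pd.DataFrame, t: float = 0.8, fdr_only: bool = True
) -> pd.DataFrame:
    kept = _passing(entries, fdr_only)
    if kept.empty:
        return kept
    return kept[kept["abs_rho"] > t]


def phylum_composition(
    entries: pd.DataFrame,
    taxonomy: pd.Series,
    t: float = 0.8,
    fdr_only: bool = True,
) -> pd.Series:
    """Per-phylum share of the correlated abundance at threshold ``t``.

    Shares are normalized to sum to 1; an empty correlated set returns an
    empty Series (not NaN).
    """
    kept = correlated_otus(entries, t=t, fdr_only=fdr_only)
    if kept.empty or kept["mean_ra"].sum() == 0:
        return pd.Series(dtype=float, name="share")
    phyla = taxonomy.loc[kept.index].map(phylum_of)
    shares = kept["mean_ra"].groupby(phyla).sum()
    shares = shares / shares.sum()
    shares.name = "share"
    return shares.sort_values(ascending=False)


# ---------------------------------------------------------------------------
# pseudo-correlation diagnostic


@dataclass(frozen=True)
class PseudoDiagnostic:
    """Outcome of comparing a factor's correlated OTUs with depth's.

    ``overlap`` is the abundance-weighted fraction of the factor's
    correlated OTUs that are also depth-correlated (shared abundance over
    the factor's correlated abundance).  Verdicts:

    * ``likely-pseudo`` — factor is strongly collinear with depth, its
      correlated OTUs are mostly depth's, and it explains no more abundance
      than depth does;
    * ``no-gradient`` — depth itself has no correlated OTUs at the
      threshold, so no comparison is possible;
    * ``no-signal`` — the factor has (almost) no correlated abundance;
    * ``possibly-direct`` — none of the above patterns.
    """

    site_id: str
    factor: str
    rho_factor_depth: float
    p_factor_depth: float
    factor_corr_abundance: float
    depth_corr_abundance: float
    overlap: float
    verdict: str
    rho_threshold: float = 0.8
    overlap_threshold: float = 0.5


def pseudo_correlation_diagnostic(
    factor_entries: pd.DataFrame,
    depth_entries: pd.DataFrame,
    env: EnvMatrix | pd.DataFrame,
    site_id: str,
    factor: str,
    *,
    rho_threshold: float = 0.8,
    overlap_threshold: float = 0.5,
    min_abundance: float = 0.01,
) -> PseudoDiagnostic:
    """Decide whether a factor's OTU correlations are likely pseudo.

    A factor whose profile tracks the depth gradient inherits OTU
    correlations from it; such correlations say nothing about a direct
    effect of the factor.  The diagnostic combines (a) the factor-depth
    Spearman correlation across layers, (b) the abundance-weighted overlap
    of the factor's and depth's |rho| > threshold OTU sets, and (c) the
    comparison of correlated abundances.
    """
    env_df = env.sites[site_id] if isinstance(env, EnvMatrix) else env
    res = spearman(env_df[factor].to_numpy(), env_df.index.to_numpy())
    fac_set = correlated_otus(factor_entries, t=rho_threshold)
    dep_set = correlated_otus(depth_entries, t=rho_threshold)
    fac_ab = float(fac_set["mean_ra"].sum()) if len(fac_set) else 0.0
    dep_ab = float(dep_set["mean_ra"].sum()) if len(dep_set) else 0.0
    shared = set(fac_set.index) & set(dep_set.index)
    shared_ab = float(fac_set.loc[list(shared), "mean_ra"].sum()) if shared else 0.0
    overlap = shared_ab / fac_ab if fac_ab > 0 else 0.0

    if dep_set.empty:
        verdict = "no-gradient"
    elif fac_ab < min_abundance:
        verdict = "no-signal"
    elif (
        np.isfinite(res.rho)
        and abs(res.rho) >= rho_threshold
        and overlap >= overlap_threshold
        and fac_ab <= dep_ab + 1e-12
    ):
        verdict = "likely-pseudo"
    else:
        verdict = "possibly-direct"

    return PseudoDiagnostic(
        site_id=site_id,
        factor=factor,
        rho_factor_depth=res.rho,
        p_factor_depth=res.p_value,
        factor_corr_abundance=fac_ab,
        depth_corr_abundance=dep_ab,
        overlap=overlap,
        verdict=verdict,
        rho_threshold=rho_threshold,
        overlap_threshold=overlap_threshold,
    )
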