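"""Synthetic layered-sediment community generator.

Emulates the statistical structure the screening pipeline assumes in a
lake-sediment survey: a small number of sites, each a stack of 5-cm layers
whose midpoint depth is the dominant environmental gradient; environmental
factors that are collinear with depth to a controlled degree (volumetric
water content strongly so, gas space not at all); a community of ~2,000
OTUs of which a configurable fraction responds monotonically to depth; and
an ebullition-mixing operator that blends each layer's composition toward
the site mean, mimicking the pore-water exchange driven by methane bubble
release.  Gas space influences communities *only* through mixing — the
generator plants no direct gas-space effect, so a correct screen should
find none (a built-in negative control).

Counts are drawn Dirichlet-multinomial per layer; every generator is
deterministic given the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .otu import OtuTable, write_otu_tsv, write_biom_json
from .screen import EnvMatrix, spearman
from .ordination import RootedTree, write_newick

__all__ = [
    "SimConfig",
    "LatentCommunity",
    "simulate_env",
    "simulate_community",
    "apply_mixing",
    "sample_counts",
    "simulate_tree",
    "simulate_dataset",
    "generate_fixture",
    "TOP_PHYLA",
]

#: phylum pool for synthetic taxonomy, ordered by typical abundance in
#: eutrophic lake sediment (used with geometrically decaying weights)
TOP_PHYLA = (
    "Proteobacteria",
    "Acidobacteria",
    "Chloroflexi",
    "Bacteroidetes",
    "Planctomycetes",
    "Verrucomicrobia",
    "Actinobacteria",
    "Nitrospirae",
    "Gemmatimonadetes",
    "Cyanobacteria",
)


def _default_collinearity() -> dict:
    return {
        "vwc": -0.9,
        "gas_space": 0.0,
        "p_size": {"site2": 0.33, "site3": -0.5, "site4": -0.89, "site5": 0.07},
        "p_evenness": 0.0,
    }


def _default_mixing() -> dict:
    # emission-stage proxy: strongest mixing at the river-dominated sites
    return {"site2": 0.5, "site3": 0.8, "site4": 0.2, "site5": 0.0}


@dataclass
class SimConfig:
    """Study-shaped defaults: 4 sites x 9 layers (midpoints 2.5-42.5 cm),
    2,000 OTUs, 30 % depth-responsive with a 2-nat log-fold change across
    the profile, VWC built to Spearman -0.9 with depth, gas space
    depth-independent and present only at the gas-bearing sites."""

    site_ids: tuple = ("site2", "site3", "site4", "site5")
    layers_per_site: int = 9
    depth_start_cm: float = 2.5
    depth_step_cm: float = 5.0
    n_otus: int = 2000
    responsive_fraction: float = 0.3
    effect_size: float = 2.0  # natural-log fold change across the profile
    factor_collinearity: dict = field(default_factory=_default_collinearity)
    mixing_strength: dict = field(default_factory=_default_mixing)
    gas_sites: tuple = ("site2", "site3", "site4")
    sequencing_depth: int = 50_000
    dispersion: float = 1e5  # Dirichlet concentration scale (near-multinomial)
    baseline_sigma: float = 2.0  # log-abundance spread of the species pool
    site_jitter_sigma: float = 0.3  # per-site baseline perturbation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.responsive_fraction <= 1):
            raise ValueError("responsive_fraction must lie in [0, 1]")
        for site, m in self.mixing_strength.items():
            if not (0 <= m <= 1):
                raise ValueError(f"mixing strength at {site} outside [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def depths(self) -> np.ndarray:
        return self.depth_start_cm + self.depth_step_cm * np.arange(
            self.layers_per_site
        )

    def mixing_for(self, site: str) -> float:
        return float(self.mixing_strength.get(site, 0.0))

    def collinearity_for(self, factor: str, site: str) -> float:
        tgt = self.factor_collinearity.get(factor, 0.0)
        if isinstance(tgt, dict):
            tgt = tgt.get(site, 0.0)
        return float(tgt)


@dataclass
class LatentCommunity:
    """Noise-free layer compositions per site plus the planted truth."""

    compositions: dict[str, pd.DataFrame]  # site -> layers x OTUs, rows sum to 1
    planted: pd.DataFrame  # otu_id, sign, center_cm, width_cm, effect_size
    otu_ids: list[str]

    def __post_init__(self) -> None:
        for site, comp in self.compositions.items():
            if not np.allclose(comp.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"non-simplex rows at {site}")
        if not set(self.planted["otu_id"]) <= set(self.otu_ids):
            raise ValueError("planted set is not a subset of the OTU pool")


# ---------------------------------------------------------------------------
# environmental factors


def _copula_factor(
    depths: np.ndarray,
    target: float,
    rng: np.random.Generator,
    *,
    tol: float = 0.05,
    max_tries: int = 5000,
) -> np.ndarray:
    """Standardized factor profile with realized Spearman(factor, depth)
    within ``tol`` of ``target`` (rejection-adjusted for strong targets)."""
    if abs(target) > 1:
        raise ValueError(f"unattainable Spearman target {target}")
    n = depths.size
    zd = (depths - depths.mean()) / depths.std()
    if abs(target) >= 1 - 1e-12:
        return np.sign(target) * zd
    # bivariate-normal Pearson r giving Spearman rho = target
    r = 2 * np.sin(np.pi * target / 6)
    reject = abs(target) >= 0.5
    best, best_err = None, np.inf
    for _ in range(max_tries):
        y = r * zd + np.sqrt(1 - r**2) * rng.standard_normal(n)
        if not reject:
            return y
        rho = spearman(y, depths).rho
        err = abs(rho - target)
        if err < best_err:
            best, best_err = y, err
        if err <= tol:
            return y
    return best  # closest achieved profile


def simulate_env(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[EnvMatrix, dict]:
    """Generate per-site environmental profiles.

    VWC is a decreasing function of depth with calibrated noise; gas space
    is drawn independently of depth at gas-bearing sites and is
    structurally zero elsewhere; TIS = VWC + gas space (the interstitial
    volume identity); particle size follows a per-site collinearity target
    on the log scale; evenness is depth-independent.  Returns the matrix
    and a record of realized factor-depth Spearman values.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    depths = config.depths
    sites: dict[str, pd.DataFrame] = {}
    realized: dict[str, dict[str, float]] = {}
    for site in config.site_ids:
        df = pd.DataFrame(index=pd.Index(depths, name="depth_cm"))
        df["depth"] = depths

        z = _copula_factor(depths, config.collinearity_for("vwc", site), rng)
        # map to a plausible percent range (~50-88 %)
        df["vwc"] = 68.0 + 12.0 * z / max(np.abs(z).max(), 1e-9)

        if site in config.gas_sites:
            df["gas_space"] = rng.uniform(0.0, 15.0, depths.size)
        else:
            df["gas_space"] = 0.0
        df["tis"] = df["vwc"] + df["gas_space"]

        zp = _copula_factor(depths, config.collinearity_for("p_size", site), rng)
        df["p_size"] = np.exp(np.log(30.0) + 0.8 * zp)

        ze = _copula_factor(depths, config.collinearity_for("p_evenness", site), rng)
        df["p_evenness"] = np.clip(1.2 + 0.25 * ze, 0.5, 2.0)

        sites[site] = df
        realized[site] = {
            fac: spearman(df[fac].to_numpy(), depths).rho
            for fac in ("vwc", "tis", "gas_space", "p_size", "p_evenness")
        }
    return EnvMatrix(sites=sites), realized


# ---------------------------------------------------------------------------
# community


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def simulate_community(
    config: SimConfig, rng: np.random.Generator | None = None
) -> LatentCommunity:
    """Latent (noise-free) compositions with planted depth responses.

    Baseline log-abundances come from a long-tailed normal pool shared by
    all sites (plus small per-site jitter); each responsive OTU carries a
    strictly monotone logistic depth response of full range
    ``effect_size`` nats with a random sign and random center/width.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_otus
    otu_ids = [f"OTU_{i+1:05d}" for i in range(n)]
    base = rng.normal(0.0, config.baseline_sigma, n)

    n_resp = int(round(config.responsive_fraction * n))
    resp_idx = rng.choice(n, size=n_resp, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_resp)
    depths = config.depths
    lo, hi = depths.min(), depths.max()
    centers = rng.uniform(lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo), n_resp)
    widths = rng.uniform(6.0, 15.0, n_resp)

    def _sig(d, c, w):
        return 1.0 / (1.0 + np.exp(-(d - c) / w))

    response = np.zeros((depths.size, n))
    for j, (i, s, c, w) in enumerate(zip(resp_idx, signs, centers, widths)):
        prof = _sig(depths, c, w)
        prof = (prof - prof[0]) / (prof[-1] - prof[0])  # exact 0..1 range
        response[:, i] = s * config.effect_size * prof

    compositions = {}
    for site in config.site_ids:
        jitter = rng.normal(0.0, config.site_jitter_sigma, n)
        logits = base[None, :] + jitter[None, :] + response
        compositions[site] = pd.DataFrame(
            _softmax_rows(logits),
            index=pd.Index(depths, name="depth_cm"),
            columns=otu_ids,
        )
    planted = pd.DataFrame(
        {
            "otu_id": [otu_ids[i] for i in resp_idx],
            "sign": signs,
            "center_cm": centers,
            "width_cm": widths,
            "effect_size": config.effect_size,
        }
    )
    return LatentCommunity(
        compositions=compositions, planted=planted, otu_ids=otu_ids
    )


def apply_mixing(
    latent: LatentCommunity, m: float | dict[str, float]
) -> LatentCommunity:
    """Ebullition mixing: blend each layer toward the site-mean composition.

    ``m`` in [0, 1] (scalar or per-site): 0 leaves the profile intact, 1
    homogenizes all layers to the site mean.  Rows stay on the simplex
    because mixing is a convex combination.
    """
    mixed = {}
    for site, comp in latent.compositions.items():
        ms = float(m[site] if isinstance(m, dict) else m)
        if not (0 <= ms <= 1):
            raise ValueError(f"mixing strength {ms} outside [0, 1]")
        site_mean = comp.mean(axis=0)
        mixed[site] = (1 - ms) * comp + ms * site_mean
    return LatentCommunity(
        compositions=mixed, planted=latent.planted.copy(), otu_ids=latent.otu_ids
    )


def _make_taxonomy(otu_ids: list[str], rng: np.random.Generator) -> pd.Series:
    weights = 0.72 ** np.arange(len(TOP_PHYLA))
    weights /= weights.sum()
    phyla = rng.choice(TOP_PHYLA, size=len(otu_ids), p=weights)
    lineages = [f"d__Bacteria;p__{p};c__;o__;f__;g__" for p in phyla]
    return pd.Series(lineages, index=otu_ids, name="lineage")


def sample_counts(
    latent: LatentCommunity,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> OtuTable:
    """Dirichlet-multinomial read counts at the configured sequencing depth.

    The Dirichlet concentration is ``dispersion * composition``; as
    dispersion grows the draw approaches a plain multinomial around the
    latent proportions.  Sample ids are ``<site>_L<k>``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.sequencing_depth <= 0:
        raise ValueError("sequencing_depth must be positive")
    rows, meta = [], {}
    sample_ids = []
    for site, comp in latent.compositions.items():
        for k, (depth, row) in enumerate(comp.iterrows()):
            probs = row.to_numpy(dtype=float)
            if np.isfinite(config.dispersion):
                alpha = np.maximum(config.dispersion * probs, 1e-9)
                probs = rng.dirichlet(alpha)
            counts = rng.multinomial(config.sequencing_depth, probs)
            sid = f"{site}_L{k+1}"
            sample_ids.append(sid)
            rows.append(counts)
            meta[sid] = {"site_id": site, "depth_cm": float(depth)}
    counts_df = pd.DataFrame(
        np.array(rows), index=sample_ids, columns=latent.otu_ids
    )
    taxonomy = _make_taxonomy(latent.otu_ids, rng)
    return OtuTable(
        counts=counts_df,
        sample_meta=pd.DataFrame.from_dict(meta, orient="index"),
        taxonomy=taxonomy,
    )


def simulate_tree(otu_ids, seed: int) -> RootedTree:
    """Random rooted binary tree over the OTUs, coalescent-style.

    Lineages are merged pairwise at random with exponential branch
    lengths; n leaves yield n-1 internal nodes.
    """
    otu_ids = list(otu_ids)
    if len(otu_ids) < 2:
        raise ValueError("need at least 2 OTUs for a tree")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in otu_ids:
        tip = TreeNode(name=name)
        tip.length = float(rng.exponential(0.1))
        nodes.append(tip)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(0.1))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return RootedTree(root)


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(
    config: SimConfig, mixing: float | dict | None = None
) -> dict:
    """Full in-memory dataset: environment, latent truth, counts, tree.

    ``mixing`` overrides the per-site mixing strengths of the config
    (scalar applies everywhere).  Returns a dict with keys ``env``,
    ``realized_collinearity``, ``latent``, ``mixed``, ``table``, ``tree``
    and ``truth``.
    """
    rng = np.random.default_rng(config.seed)
    env, realized = simulate_env(config, rng)
    latent = simulate_community(config, rng)
    m = config.mixing_strength if mixing is None else mixing
    mixed = apply_mixing(latent, m)
    table = sample_counts(mixed, config, rng)
    tree = simulate_tree(latent.otu_ids, seed=config.seed + 1)
    truth = {
        "seed": config.seed,
        "n_otus": config.n_otus,
        "planted_otus": latent.planted["otu_id"].tolist(),
        "planted_signs": latent.planted["sign"].tolist(),
        "effect_size": config.effect_size,
        "mixing_strength": (
            {s: (m[s] if isinstance(m, dict) else float(m)) for s in config.site_ids}
        ),
        "realized_collinearity": realized,
    }
    return {
        "env": env,
        "realized_collinearity": realized,
        "latent": latent,
        "mixed": mixed,
        "table": table,
        "tree": tree,
        "truth": truth,
    }


def generate_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic dataset to ``outdir``.

    Files: env.tsv (long format), otu_counts.tsv + sample_meta.tsv +
    taxonomy.tsv, otu_table.biom.json, tree.nwk and truth.json with the
    planted parameters.  Byte-identical across reruns with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config)
    env: EnvMatrix = ds["env"]
    long_rows = []
    for site, df in env.sites.items():
        for depth, row in df.iterrows():
            for fac in ("vwc", "tis", "gas_space", "p_size", "p_evenness"):
                long_rows.append(
                    {
                        "site_id": site,
                        "depth_cm": float(depth),
                        "variable": fac,
                        "value": float(row[fac]),
                    }
                )
    paths = {
        "env": outdir / "env.tsv",
        "counts": outdir / "otu_counts.tsv",
        "meta": outdir / "sample_meta.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "biom": outdir / "otu_table.biom.json",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "truth.json",
    }
    pd.DataFrame(long_rows).to_csv(paths["env"], sep="\t", index=False)
    write_otu_tsv(ds["table"], paths["counts"], paths["meta"], paths["taxonomy"])
    write_biom_json(ds["table"], paths["biom"])
    write_newick(ds["tree"], paths["tree"])
    with open(paths["truth"], "w") as fh:
        json.dump(ds["truth"], fh, indent=1, sort_keys=True)
    return paths
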