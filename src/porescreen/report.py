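"""End-to-end pipeline driver and report bundle.

`run_pipeline` chains the library stages on one dataset and writes every
result as plain TSV/JSON so downstream plotting never needs to re-run
statistics: physics range summary, top-phyla composition, PCoA coordinates
and PERMANOVA per site, per-(site, factor) screen tables with threshold
curves and phylum compositions, the RDA factor table, and the
pseudo-correlation diagnostic.  A machine-readable manifest records seeds,
thresholds and a config hash so identical configurations produce
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .otu import OtuTable, aggregate_phylum, preprocess, relative_abundance
from .ordination import (
    RootedTree,
    factor_fit,
    pcoa,
    permanova,
    rda,
    unifrac_matrix,
    write_distance_tsv,
)
from .physics import read_layer_table, summarize_profiles
from .screen import (
    FACTORS,
    EnvMatrix,
    correlated_abundance_at,
    phylum_composition,
    pseudo_correlation_diagnostic,
    screen_all,
    threshold_curve,
)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    """Thresholds, seeds and switches for one pipeline run."""

    out_dir: Path
    p_gate: float = 0.05
    fdr_alpha: float = 0.05
    rho_threshold: float = 0.8
    rarefaction_depth: int | str = "min"
    n_permutations: int = 999
    seed: int = 0
    stages: tuple = ("physics", "preprocess", "screen", "ordinate", "diagnose")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("p_gate", "fdr_alpha", "rho_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name}={v} outside (0, 1)")
        self.out_dir = Path(self.out_dir)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                k: str(v)
                for k, v in dataclasses.asdict(self).items()
                if k != "out_dir"  # analytic settings only, not location
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", na_rep="NA")


def run_pipeline(
    config: RunConfig,
    *,
    table: OtuTable,
    env: EnvMatrix,
    tree: RootedTree | None = None,
    physics_table: pd.DataFrame | None = None,
) -> dict:
    """Run the configured stages and write the report bundle.

    Returns a dict of in-memory results keyed like the written artifacts.
    Any stage failure propagates with the stage name prepended.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "setup"
    try:
        if "physics" in config.stages and physics_table is not None:
            stage = "physics"
            summary = summarize_profiles(physics_table)
            _write_tsv(summary, out / "physics_summary.tsv")
            results["physics_summary"] = summary

        stage = "preprocess"
        clean, prep_report = preprocess(
            table, rarefaction_depth=config.rarefaction_depth, seed=config.seed
        )
        ra = relative_abundance(clean)
        phyla = aggregate_phylum(ra, top_k=10)
        _write_tsv(phyla, out / "phylum_barchart.tsv")
        results["phylum_barchart"] = phyla

        if "screen" in config.stages:
            stage = "screen"
            screens = screen_all(
                ra, env, p_gate=config.p_gate, fdr_alpha=config.fdr_alpha
            )
            results["screens"] = screens
            curve_rows, comp_rows, screen_frames = [], [], []
            for (site, fac), entries in screens.items():
                df = entries.copy()
                df.insert(0, "factor", fac)
                df.insert(0, "site_id", site)
                screen_frames.append(df.reset_index())
                curve = threshold_curve(entries)
                curve_rows.append(
                    pd.DataFrame(
                        {
                            "site_id": site,
                            "factor": fac,
                            "threshold": curve.thresholds,
                            "yra": curve.yra,
                        }
                    )
                )
                comp = phylum_composition(
                    entries, ra.taxonomy, t=config.rho_threshold
                )
                for phylum, share in comp.items():
                    comp_rows.append(
                        {
                            "site_id": site,
                            "factor": fac,
                            "phylum": phylum,
                            "share": share,
                        }
                    )
            non_empty = [f for f in screen_frames if len(f)]
            _write_tsv(
                (
                    pd.concat(non_empty, ignore_index=True)
                    if non_empty
                    else screen_frames[0]
                ).set_index("otu_id"),
                out / "screen_entries.tsv",
            )
            _write_tsv(
                pd.concat(curve_rows, ignore_index=True).set_index("site_id"),
                out / "threshold_curves.tsv",
            )
            _write_tsv(
                pd.DataFrame(comp_rows).set_index("site_id")
                if comp_rows
                else pd.DataFrame(columns=["site_id", "factor", "phylum", "share"]),
                out / "correlated_phyla.tsv",
            )

        if "ordinate" in config.stages:
            stage = "ordinate"
            perm_rows, coord_frames = [], []
            if tree is not None:
                presence = clean.counts > 0
                dist = unifrac_matrix(tree, presence)
                write_distance_tsv(dist, out / "unifrac_distances.tsv")
                results["unifrac"] = dist
                for site in env.sites:
                    ids = clean.sample_meta.index[
                        clean.sample_meta["site_id"] == site
                    ]
                    sub = dist.loc[ids, ids]
                    coords = pcoa(sub).coordinates
                    coords.insert(0, "site_id", site)
                    coord_frames.append(coords)
                labels = clean.sample_meta["site_id"]
                res = permanova(
                    dist,
                    labels.loc[dist.index],
                    n_perm=config.n_permutations,
                    seed=config.seed,
                )
                perm_rows.append(
                    {
                        "grouping": "site",
                        "pseudo_f": res.pseudo_f,
                        "r2": res.r2,
                        "p_value": res.p_value,
                        "permutations": res.n_permutations,
                    }
                )
                _write_tsv(
                    pd.concat(coord_frames).rename_axis("sample_id"),
                    out / "pcoa_coordinates.tsv",
                )
                _write_tsv(
                    pd.DataFrame(perm_rows).set_index("grouping"),
                    out / "permanova.tsv",
                )
                results["permanova"] = perm_rows

            # RDA across all samples: depth-aligned factor matrix
            meta = clean.sample_meta
            fac_rows = []
            for sid in meta.index:
                site, depth = meta.loc[sid, "site_id"], meta.loc[sid, "depth_cm"]
                env_df = env.sites[site]
                i = int(np.argmin(np.abs(env_df.index.to_numpy() - depth)))
                fac_rows.append(env_df.iloc[i][list(FACTORS)].to_dict())
            X = pd.DataFrame(fac_rows, index=meta.index)
            ok = X.notna().all(axis=1)
            Y = ra.proportions.loc[ok.index[ok]]
            Xo = X.loc[ok]
            joint = rda(Y.to_numpy(), Xo.to_numpy())
            ratio = (
                joint.adj_r2 / joint.r2 if joint.r2 and joint.r2 > 0 else None
            )
            fits = []
            for k, fac in enumerate(FACTORS):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ff = factor_fit(
                        Y.to_numpy(),
                        Xo[fac].to_numpy(),
                        name=fac,
                        n_perm=config.n_permutations,
                        seed=config.seed + k,
                        joint_axes=joint.coordinates.iloc[:, :2],
                        model_adj_ratio=ratio,
                    )
                fits.append(dataclasses.asdict(ff))
            rda_table = pd.DataFrame(fits).set_index("factor")
            rda_table.attrs["model_r2"] = joint.r2
            rda_table.attrs["model_adj_r2"] = joint.adj_r2
            _write_tsv(rda_table, out / "rda_factor_table.tsv")
            results["rda_table"] = rda_table
            results["rda_model"] = joint

        if "diagnose" in config.stages and "screens" in results:
            stage = "diagnose"
            diag_rows = []
            screens = results["screens"]
            for site in env.sites:
                depth_entries = screens.get((site, "depth"))
                if depth_entries is None:
                    continue
                for fac in FACTORS:
                    if fac == "depth" or (site, fac) not in screens:
                        continue
                    diag = pseudo_correlation_diagnostic(
                        screens[(site, fac)],
                        depth_entries,
                        env,
                        site,
                        fac,
                        rho_threshold=config.rho_threshold,
                    )
                    diag_rows.append(dataclasses.asdict(diag))
            diag_df = pd.DataFrame(diag_rows).set_index(["site_id", "factor"])
            _write_tsv(diag_df, out / "pseudo_diagnostic.tsv")
            with open(out / "pseudo_diagnostic.json", "w") as fh:
                json.dump(diag_rows, fh, indent=1)
            results["diagnostics"] = diag_rows

        stage = "manifest"
        manifest = {
            "porescreen_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "p_gate": config.p_gate,
            "fdr_alpha": config.fdr_alpha,
            "rho_threshold": config.rho_threshold,
            "n_permutations": config.n_permutations,
            "preprocess": {
                k: v
                for k, v in prep_report.items()
                if k not in ("low_abundance_removed", "organelles_removed")
            },
            "stages": list(config.stages),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        results["manifest"] = manifest
    except Exception as exc:  # re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def validate_inputs(
    table: OtuTable | None = None,
    env: EnvMatrix | None = None,
    tree: RootedTree | None = None,
) -> list[str]:
    """Cross-consistency report (sample/OTU ids, depth ordering).

    Returns a list of human-readable problems; empty means clean.  Never
    raises — this is a report-only check.
    """
    problems: list[str] = []
    if table is not None:
        if table.sample_meta["depth_cm"].isna().any():
            problems.append("samples with missing depth_cm")
        for site, grp in table.sample_meta.groupby("site_id"):
            depths = grp["depth_cm"].to_numpy(dtype=float)
            if len(np.unique(depths)) != len(depths):
                problems.append(f"duplicate sample depths at {site}")
    if table is not None and env is not None:
        table_sites = set(table.sample_meta["site_id"])
        env_sites = set(env.sites)
        for site in sorted(table_sites - env_sites):
            problems.append(f"site {site} has samples but no environmental rows")
        for site in table_sites & env_sites:
            env_depths = env.sites[site].index.to_numpy(dtype=float)
            sample_depths = table.sample_meta.loc[
                table.sample_meta["site_id"] == site, "depth_cm"
            ].to_numpy(dtype=float)
            for d in sample_depths:
                if not np.any(np.isclose(env_depths, d)):
                    problems.append(
                        f"sample depth {d} cm at {site} missing from env table"
                    )
    if table is not None and tree is not None:
        missing = set(table.otu_ids) - set(tree.leaf_names)
        for otu in sorted(missing)[:20]:
            problems.append(f"OTU {otu} absent from tree")
        if len(missing) > 20:
            problems.append(f"... and {len(missing) - 20} more OTUs absent from tree")
    return problems
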