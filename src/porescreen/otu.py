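"""OTU count-table container, cleanup pipeline and I/O.

The analysis takes an annotated OTU table (samples from four sites, nine
5-cm layers each) and applies the standard post-annotation cleanup before
any statistics: a dataset-wide low-abundance filter (relative abundance
below 0.005 % of all reads), removal of chloroplast / mitochondrial
lineages, and rarefaction of every sample to a common read depth by
subsampling without replacement.  Counts live in a pandas DataFrame of
shape (samples x OTUs); sample metadata carries site and depth.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "RelAbundanceTable",
    "FilterReport",
    "filter_low_abundance",
    "remove_organelles",
    "rarefy",
    "relative_abundance",
    "aggregate_phylum",
    "phylum_of",
    "preprocess",
    "read_otu_tsv",
    "write_otu_tsv",
    "read_biom_json",
    "write_biom_json",
    "read_taxonomy_tsv",
    "write_taxonomy_tsv",
]

_RANK_PREFIX = re.compile(r"^[a-zA-Z]__")
_ORGANELLE = re.compile(r"chloroplast|mitochondria", re.IGNORECASE)


@dataclass
class OtuTable:
    """Counts (samples x OTUs) with per-sample site/depth and OTU lineages.

    ``counts`` columns are OTU ids; ``sample_meta`` is indexed by sample id
    with columns ``site_id`` and ``depth_cm``; ``taxonomy`` maps OTU id to a
    Silva-style lineage string (possibly partially unassigned, never absent).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        if not (self.counts.values >= 0).all():
            raise ValueError("counts must be non-negative")
        if not set(self.counts.index) <= set(self.sample_meta.index):
            missing = set(self.counts.index) - set(self.sample_meta.index)
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        for col in ("site_id", "depth_cm"):
            if col not in self.sample_meta.columns:
                raise ValueError(f"sample_meta lacks column {col!r}")
        missing_tax = set(self.counts.columns) - set(self.taxonomy.index)
        if missing_tax:
            raise ValueError(f"OTUs without lineage: {sorted(missing_tax)[:5]}")
        self.sample_meta = self.sample_meta.loc[self.counts.index]
        self.taxonomy = self.taxonomy.loc[self.counts.columns]

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def subset_otus(self, keep: list[str]) -> "OtuTable":
        return OtuTable(
            counts=self.counts[keep].copy(),
            sample_meta=self.sample_meta.copy(),
            taxonomy=self.taxonomy.loc[keep].copy(),
        )


@dataclass
class RelAbundanceTable:
    """Per-sample OTU proportions; every row sums to 1."""

    proportions: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        sums = self.proportions.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)].index.tolist()
            raise ValueError(f"rows do not sum to 1: {bad[:5]}")

    def site(self, site_id: str) -> "RelAbundanceTable":
        """Restrict to one site, rows ordered by increasing depth."""
        meta = self.sample_meta[self.sample_meta["site_id"] == site_id]
        meta = meta.sort_values("depth_cm")
        return RelAbundanceTable(
            proportions=self.proportions.loc[meta.index],
            sample_meta=meta,
            taxonomy=self.taxonomy,
        )


@dataclass
class FilterReport:
    removed: list[str] = field(default_factory=list)
    reason: str = ""


def filter_low_abundance(
    table: OtuTable, threshold: float = 5e-5
) -> tuple[OtuTable, FilterReport]:
    """Drop OTUs whose dataset-wide relative abundance is below ``threshold``.

    The share is the OTU's total count over the grand total; an OTU exactly
    at the threshold is kept.  ``threshold=0`` disables the filter.
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    grand = table.counts.values.sum()
    if grand <= 0:
        raise ValueError("empty table: grand total is zero")
    if threshold == 0:
        return table, FilterReport(reason="threshold 0: filter disabled")
    share = table.counts.sum(axis=0) / grand
    removed = share.index[share < threshold].tolist()
    keep = [o for o in table.otu_ids if o not in set(removed)]
    report = FilterReport(
        removed=removed,
        reason=f"dataset-wide relative abundance < {threshold:g}",
    )
    return table.subset_otus(keep), report


def remove_organelles(table: OtuTable) -> tuple[OtuTable, FilterReport]:
    """Drop OTUs whose lineage mentions chloroplast or mitochondria."""
    hits = table.taxonomy[table.taxonomy.str.contains(_ORGANELLE, na=False)]
    keep = [o for o in table.otu_ids if o not in set(hits.index)]
    report = FilterReport(
        removed=hits.index.tolist(), reason="chloroplast/mitochondria lineage"
    )
    return table.subset_otus(keep), report


def rarefy(table: OtuTable, depth: int | str = "min", seed: int | None = None) -> OtuTable:
    """Subsample every sample without replacement to a common read depth.

    ``depth="min"`` uses the smallest sample total.  Drawing is a
    multivariate hypergeometric per sample, i.e. exactly the classical
    rarefaction of reads; deterministic for a fixed ``seed``.
    """
    totals = table.counts.sum(axis=1)
    if isinstance(depth, str):
        if depth != "min":
            raise ValueError("depth must be an integer or 'min'")
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    too_small = totals.index[totals < depth].tolist()
    if too_small:
        raise ValueError(
            f"samples shallower than depth {depth}: {too_small[:10]}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.values)
    for i, row in enumerate(table.counts.values.astype(np.int64)):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return OtuTable(counts=counts, sample_meta=table.sample_meta.copy(),
                    taxonomy=table.taxonomy.copy())


def relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Convert counts to per-sample proportions (RA_OTU)."""
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-total samples: {zero}")
    props = table.counts.div(totals, axis=0)
    return RelAbundanceTable(
        proportions=props,
        sample_meta=table.sample_meta.copy(),
        taxonomy=table.taxonomy.copy(),
    )


def phylum_of(lineage: str) -> str:
    """Extract the phylum from a Silva-style lineage string.

    Accepts both ``d__Bacteria;p__Proteobacteria;...`` and bare
    rank-by-position lineages (second field = phylum).  Anything
    unparseable maps to ``"Unassigned"``.
    """
    if not isinstance(lineage, str) or not lineage.strip():
        return "Unassigned"
    parts = [p.strip() for p in lineage.split(";")]
    for part in parts:
        if part.lower().startswith("p__"):
            name = part[3:].strip()
            return name if name else "Unassigned"
    if any(_RANK_PREFIX.match(p) for p in parts):
        return "Unassigned"  # prefixed dialect but no phylum rank
    if len(parts) >= 2 and parts[1]:
        return parts[1]
    return "Unassigned"


def aggregate_phylum(ra: RelAbundanceTable, top_k: int = 10) -> pd.DataFrame:
    """Sum proportions by phylum; keep the ``top_k`` by dataset-wide mean.

    Returns a (phylum x sample) frame whose columns each sum to 1; phyla
    beyond the top ``top_k`` are pooled into ``"Others"``.
    """
    phyla = ra.taxonomy.map(phylum_of)
    by_phylum = ra.proportions.T.groupby(phyla.loc[ra.proportions.columns]).sum()
    order = by_phylum.mean(axis=1).sort_values(ascending=False)
    top = order.index[:top_k].tolist()
    rest = [p for p in by_phylum.index if p not in set(top)]
    out = by_phylum.loc[top]
    if rest:
        out = pd.concat([out, by_phylum.loc[rest].sum().to_frame("Others").T])
    out.index.name = "phylum"
    return out


def preprocess(
    table: OtuTable,
    *,
    abundance_threshold: float = 5e-5,
    rarefaction_depth: int | str = "min",
    seed: int | None = None,
) -> tuple[OtuTable, dict]:
    """Full cleanup in the fixed order: abundance filter, organelle removal,
    rarefaction.  Returns the cleaned table and a report dict."""
    filtered, rep1 = filter_low_abundance(table, abundance_threshold)
    no_org, rep2 = remove_organelles(filtered)
    rarefied = rarefy(no_org, depth=rarefaction_depth, seed=seed)
    report = {
        "low_abundance_removed": rep1.removed,
        "organelles_removed": rep2.removed,
        "n_otus_in": len(table.otu_ids),
        "n_otus_out": len(rarefied.otu_ids),
        "rarefaction_depth": int(rarefied.counts.sum(axis=1).iloc[0]),
        "seed": seed,
    }
    return rarefied, report


# ---------------------------------------------------------------------------
# I/O: TSV (either orientation) and BIOM-style JSON


def read_otu_tsv(
    counts_path: str | Path,
    meta_path: str | Path,
    taxonomy_path: str | Path,
) -> OtuTable:
    """Read counts, sample metadata and taxonomy from TSV files.

    The counts table may be samples x OTUs or OTUs x samples; orientation is
    auto-detected by matching the header / index against the metadata's
    sample ids.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    tax = read_taxonomy_tsv(taxonomy_path)
    samples = set(meta.index.astype(str))
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    cols_are_samples = len(samples & set(counts.columns)) > len(
        samples & set(counts.index)
    )
    if cols_are_samples:
        counts = counts.T
    return OtuTable(counts=counts.astype(np.int64), sample_meta=meta, taxonomy=tax)


def write_otu_tsv(table: OtuTable, counts_path, meta_path, taxonomy_path) -> None:
    table.counts.rename_axis("sample_id").to_csv(counts_path, sep="\t")
    table.sample_meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")
    write_taxonomy_tsv(table.taxonomy, taxonomy_path)


def read_taxonomy_tsv(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy TSV needs columns: otu_id, lineage")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="lineage")
    return ser.fillna("Unassigned")


def write_taxonomy_tsv(taxonomy: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"otu_id": taxonomy.index, "lineage": taxonomy.values}).to_csv(
        path, sep="\t", index=False
    )


def read_biom_json(path: str | Path) -> OtuTable:
    """Read a BIOM v1.0 (JSON, dense or sparse) OTU table.

    Expects per-observation ``taxonomy`` metadata and per-sample ``site_id``
    and ``depth_cm`` metadata.
    """
    with open(path) as fh:
        doc = json.load(fh)
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    mat = np.zeros((n_obs, n_samp))
    if doc.get("matrix_type") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    counts = pd.DataFrame(mat.T, index=sample_ids, columns=otu_ids).astype(np.int64)
    lineages = {}
    for r in doc["rows"]:
        tax = (r.get("metadata") or {}).get("taxonomy", "Unassigned")
        if isinstance(tax, list):
            tax = ";".join(tax)
        lineages[r["id"]] = tax
    meta_rows = {}
    for c in doc["columns"]:
        md = c.get("metadata") or {}
        meta_rows[c["id"]] = {
            "site_id": md.get("site_id", ""),
            "depth_cm": float(md.get("depth_cm", np.nan)),
        }
    return OtuTable(
        counts=counts,
        sample_meta=pd.DataFrame.from_dict(meta_rows, orient="index"),
        taxonomy=pd.Series(lineages, name="lineage"),
    )


def write_biom_json(table: OtuTable, path: str | Path) -> None:
    """Write a BIOM v1.0 sparse-JSON OTU table with embedded metadata."""
    counts = table.counts.T  # BIOM is observations x samples
    data = [
        [int(i), int(j), int(v)]
        for (i, j), v in np.ndenumerate(counts.values)
        if v != 0
    ]
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "porescreen",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [counts.shape[0], counts.shape[1]],
        "rows": [
            {"id": o, "metadata": {"taxonomy": table.taxonomy[o]}}
            for o in counts.index
        ],
        "columns": [
            {
                "id": s,
                "metadata": {
                    "site_id": str(table.sample_meta.loc[s, "site_id"]),
                    "depth_cm": float(table.sample_meta.loc[s, "depth_cm"]),
                },
            }
            for s in counts.columns
        ],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
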