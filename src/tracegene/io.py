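"""Readers and writers for the on-disk formats.

TSV is the lingua franca: counts as genes x samples with a header row of
sample ids (GCT 1.2 also accepted for expression), a 2-column sample ->
tissue map, 2-column PPI edge lists (deduplicated, self loops dropped),
2-column GO annotations, 3-column paralog pairs, long-format eQTL tables,
disease-gene-tissue associations, and patient candidate lists (TSV or JSON).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortBundle, CohortConfig, CohortTruth, EffectSizes, PatientCase
from .expression import CountMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_gct(path: str | Path) -> pd.DataFrame:
    """GCT 1.2: '#1.2' line, dimensions line, then Name/Description + samples."""
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError("GCT line 2 must hold two dimensions")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t")
    if df.shape[0] != n_rows or df.shape[1] - 2 != n_cols:
        raise ValueError(
            f"GCT dimension mismatch: header says {n_rows}x{n_cols}, "
            f"data is {df.shape[0]}x{df.shape[1] - 2} (line 2)"
        )
    df = df.set_index(df.columns[0]).drop(columns=df.columns[1])
    df.index.name = "gene"
    return df


def write_gct(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="Name")


def read_tissue_map(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="tissue")


def write_tissue_map(tissue_of: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": tissue_of.index, "tissue": tissue_of.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# secondary inputs


def read_edges(path: str | Path) -> pd.DataFrame:
    """Undirected edge list; duplicates (either orientation) collapsed and
    self loops dropped with a warning."""
    df = pd.read_csv(path, sep="\t")
    a, b = df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)
    loops = a == b
    if loops.any():
        logger.warning("dropping %d self loop(s) from edge list", int(loops.sum()))
    lo = np.where(a < b, a, b)[~loops.values]
    hi = np.where(a < b, b, a)[~loops.values]
    out = pd.DataFrame({"gene_a": lo, "gene_b": hi}).drop_duplicates(ignore_index=True)
    return out


def read_go_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(columns=dict(zip(df.columns[:2], ["term", "gene"])))


def read_paralogs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=dict(zip(df.columns[:3], ["gene_a", "gene_b", "identity"])))
    df["identity"] = df["identity"].astype(float)
    return df


def read_eqtl(path: str | Path) -> pd.DataFrame:
    """Long format (gene, tissue, q) -> genes x tissues with NaN gaps."""
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns=dict(zip(df.columns[:3], ["gene", "tissue", "q"])))
    return df.pivot_table(index="gene", columns="tissue", values="q", aggfunc="first")


def write_eqtl(eqtl_q: pd.DataFrame, path: str | Path) -> None:
    long = eqtl_q.stack().rename("q").reset_index()
    long.columns = ["gene", "tissue", "q"]
    long.to_csv(path, sep="\t", index=False)


def read_associations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.rename(
        columns=dict(zip(df.columns[:3], ["disease_id", "gene", "tissue"]))
    )


def read_brain_associations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(
        columns=dict(zip(df.columns[:4], ["disease_id", "gene", "region", "confidence"]))
    )
    df["confidence"] = df["confidence"].astype(int)
    return df


def read_patients(path: str | Path) -> list[PatientCase]:
    """TSV (patient_id, tissue, gene[, verified]) or a JSON case list."""
    path = Path(path)
    if path.suffix == ".json":
        data = json.loads(path.read_text())
        return [PatientCase(**case) for case in data]
    df = pd.read_csv(path, sep="\t")
    cases = []
    for pid, sub in df.groupby(df.columns[0], sort=True):
        tissues = sorted(sub.iloc[:, 1].unique())
        candidates = list(dict.fromkeys(sub.iloc[:, 2]))
        verified = None
        if df.shape[1] > 3:
            flagged = sub[sub.iloc[:, 3].astype(bool)]
            if len(flagged):
                verified = str(flagged.iloc[0, 2])
        cases.append(
            PatientCase(
                patient_id=str(pid),
                affected_tissues=tissues,
                candidates=candidates,
                verified_gene=verified,
            )
        )
    return cases


def write_patients(cases: list[PatientCase], path: str | Path) -> None:
    Path(path).write_text(json.dumps([dataclasses.asdict(c) for c in cases], indent=1))


# ---------------------------------------------------------------------------
# cohort bundles


def write_bundle(bundle: CohortBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts_tsv(bundle.counts.values, outdir / "counts.tsv")
    write_tissue_map(bundle.counts.tissue_of, outdir / "tissue_map.tsv")
    dev = bundle.dev_expression.copy()
    dev.columns = ["|".join(c) for c in dev.columns]
    dev.to_csv(outdir / "dev_expression.tsv", sep="\t", index_label="gene")
    bundle.ppi_edges.to_csv(outdir / "ppi_edges.tsv", sep="\t", index=False)
    bundle.go_annotations.to_csv(outdir / "go_annotations.tsv", sep="\t", index=False)
    bundle.paralogs.to_csv(outdir / "paralogs.tsv", sep="\t", index=False)
    write_eqtl(bundle.eqtl_q, outdir / "eqtl.tsv")
    bundle.associations.to_csv(outdir / "associations.tsv", sep="\t", index=False)
    bundle.brain_associations.to_csv(
        outdir / "brain_associations.tsv", sep="\t", index=False
    )
    (outdir / "truth.json").write_text(json.dumps(dataclasses.asdict(bundle.truth)))
    cfg = dataclasses.asdict(bundle.config)
    (outdir / "cohort_config.json").write_text(json.dumps(cfg))


def read_bundle(indir: str | Path) -> CohortBundle:
    indir = Path(indir)
    counts = read_counts_tsv(indir / "counts.tsv")
    tissue_of = read_tissue_map(indir / "tissue_map.tsv")
    dev = pd.read_csv(indir / "dev_expression.tsv", sep="\t", index_col="gene")
    dev.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split("|")) for c in dev.columns],
        names=["organ", "timepoint", "sample"],
    )
    cfg_raw = json.loads((indir / "cohort_config.json").read_text())
    cfg_raw["tissues"] = tuple(cfg_raw["tissues"])
    cfg_raw["go_term_size_range"] = tuple(cfg_raw["go_term_size_range"])
    cfg_raw["effect_sizes"] = EffectSizes(**cfg_raw["effect_sizes"])
    config = CohortConfig(**cfg_raw)
    truth = CohortTruth(**json.loads((indir / "truth.json").read_text()))
    return CohortBundle(
        counts=CountMatrix(values=counts, tissue_of=tissue_of),
        dev_expression=dev,
        ppi_edges=read_edges(indir / "ppi_edges.tsv"),
        go_annotations=read_go_annotations(indir / "go_annotations.tsv"),
        paralogs=read_paralogs(indir / "paralogs.tsv"),
        eqtl_q=pd.read_csv(indir / "eqtl.tsv", sep="\t")
        .pivot_table(index="gene", columns="tissue", values="q", aggfunc="first")
        .reindex(counts.index),
        associations=read_associations(indir / "associations.tsv"),
        brain_associations=read_brain_associations(indir / "brain_associations.tsv"),
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# run manifests


def config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(outdir: str | Path, stage: str, payload: dict) -> None:
    from . import __version__

    record = {
        "stage": stage,
        "config": payload,
        "config_hash": config_hash(payload),
        "version": __version__,
    }
    Path(outdir, f"{stage}_manifest.json").write_text(json.dumps(record, indent=1))
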