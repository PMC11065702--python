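"""Readers and writers for the tabular formats the pipeline touches.

Counts travel as TSV (first column ``gene_id``, remaining columns sample
ids), sample sheets as CSV, gene sets as GMT, results as TSV.  Gene
identifiers are opaque strings; no annotation mapping is performed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)


class GeneSetCollection(dict):
    """Named gene sets: mapping set name -> list of gene ids, with an
    optional description per set in :attr:`descriptions`."""

    def __init__(self, sets=None, descriptions=None):
        super().__init__(sets or {})
        self.descriptions: dict[str, str] = dict(descriptions or {})


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample integer count matrix from TSV.

    Raises on duplicate gene or sample ids, negative values, and
    non-numeric entries (the error names the offending gene and sample).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate gene ids in {path}: {dupes}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        sample = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"non-numeric count for gene {gene!r}, sample {sample!r} in {path}"
        )
    neg = numeric < 0
    if neg.any().any():
        gene = neg.index[neg.any(axis=1)][0]
        sample = neg.columns[neg.loc[gene]][0]
        raise ValueError(
            f"negative count ({numeric.loc[gene, sample]}) for gene {gene!r}, "
            f"sample {sample!r} in {path}"
        )
    frac = numeric != numeric.round()
    if frac.any().any():
        gene = frac.index[frac.any(axis=1)][0]
        sample = frac.columns[frac.loc[gene]][0]
        raise ValueError(
            f"non-integer count for gene {gene!r}, sample {sample!r} in {path}"
        )
    out = numeric.astype("int64")
    logger.info("read %d genes x %d samples from %s", *out.shape, path)
    return out


def write_counts(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id")
    logger.info("wrote %d genes x %d samples to %s", *matrix.shape, path)


def read_samples(path) -> pd.DataFrame:
    """Read a sample sheet (CSV) indexed by ``sample_id``."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate sample ids in {path}: {dupes}")
    logger.info("read %d samples from %s", len(df), path)
    return df


def write_samples(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, index_label="sample_id")
    logger.info("wrote %d samples to %s", len(sheet), path)


def read_table(path) -> pd.DataFrame:
    """Read a generic results/metrics TSV with a header row."""
    df = pd.read_csv(path, sep="\t")
    logger.info("read %d rows from %s", len(df), path)
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
    logger.info("wrote %d rows to %s", len(df), path)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT gene-set file: one set per tab-separated line of
    ``name, description, gene...``.

    Duplicate genes within a line are deduplicated with a warning; duplicate
    set names and lines with fewer than three fields are errors.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: %d duplicate gene(s) removed from set %r",
                    path, lineno, len(genes) - len(deduped), name,
                )
            sets[name] = deduped
            descriptions[name] = desc
    logger.info("read %d gene sets from %s", len(sets), path)
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
    logger.info("wrote %d gene sets to %s", len(collection), path)


#: Default analysis thresholds; every value can be overridden from a YAML
#: config file via :func:`load_config`.
DEFAULT_CONFIG: dict = {
    "qc": {
        "rna": {"min_reads": 1e6, "min_alignment_rate": 0.5, "min_exome_rate": 0.3},
        "atac": {
            "min_reads": 5e6,
            "min_peaks": 1e3,
            "min_alignment_rate": 0.5,
            "min_frip": 0.025,
        },
        "cultured_cutoff": 0.5,
    },
    "fit": {"alpha": 0.05, "lfc_cut_strong": 2.0, "lfc_cut_fc2": 1.0},
    "classify": {"alpha": 0.05, "ratio": 2.0},
    "modules": {"k": 15, "steps": 4, "padj_cut": 0.05, "lfc_cut": 2.0},
    "enrich": {"n_perm": 1000, "n_draws": 10000, "exponent": 1.0},
}


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_update(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path=None) -> dict:
    """Load analysis configuration, overlaying a YAML file (if given) on the
    built-in defaults."""
    if path is None:
        return {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULT_CONFIG.items()}
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_update(DEFAULT_CONFIG, user)
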