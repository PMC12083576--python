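"""Readers and writers for the on-disk formats.

All tabular formats are tab-separated text.  Genotypes are sample-by-
variant with a header of variant ids; phenotypes sample-by-trait with a
header of trait ids; summary statistics follow the conventional
``variant_id  chrom  pos  ref  alt  z  N`` schema (``beta``/``se`` columns
are accepted in place of ``z``); LD is a square matrix with a header row
of variant ids, or a sparse 3-column triplet file.  Variant ids are
``chrom:pos:ref:alt`` strings with 1-based inclusive coordinates when
positional information exists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TraitDataset, LDReference
from .sumstats import SummaryStats

__all__ = [
    "read_genotypes",
    "read_phenotypes",
    "read_summary_stats",
    "read_ld",
    "load_inputs",
    "write_results",
    "write_simulation",
]


class InputError(ValueError):
    """A malformed input file, with the offending file named."""


def read_genotypes(path):
    """Sample-by-variant dosage table -> (matrix, variant ids)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] == 0:
        raise InputError(f"{path}: empty genotype table")
    try:
        X = df.to_numpy(dtype=float)
    except ValueError as e:
        raise InputError(f"{path}: non-numeric dosage entry ({e})") from e
    ids = [str(c) for c in df.columns]
    if len(set(ids)) != len(ids):
        raise InputError(f"{path}: duplicate variant ids")
    return X, ids


def read_phenotypes(path):
    """Sample-by-trait phenotype table -> (matrix, trait ids)."""
    df = pd.read_csv(path, sep="\t")
    try:
        Y = df.to_numpy(dtype=float)
    except ValueError as e:
        raise InputError(f"{path}: non-numeric phenotype entry ({e})") from e
    return Y, [str(c) for c in df.columns]


def read_summary_stats(path, trait_id=None):
    """Summary-statistics table -> SummaryStats.

    Requires ``variant_id``, ``N`` and either ``z`` or both ``beta`` and
    ``se``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("variant_id", "N"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column '{col}'")
    if trait_id is None:
        trait_id = Path(path).stem
    n = int(df["N"].iloc[0])
    ids = df["variant_id"].astype(str).tolist()
    if "z" in df.columns:
        return SummaryStats(trait_id, ids, df["z"].to_numpy(float), n)
    if "beta" in df.columns and "se" in df.columns:
        return SummaryStats.from_beta_se(
            trait_id, ids, df["beta"].to_numpy(float),
            df["se"].to_numpy(float), n)
    raise InputError(f"{path}: need a 'z' column or 'beta' and 'se' columns")


def read_ld(path, atol=1e-6):
    """Square LD matrix (header row of variant ids) or sparse triplets."""
    df = pd.read_csv(path, sep="\t")
    cols = [str(c) for c in df.columns]
    if len(cols) == 3 and cols[0] != cols[1]:  # triplet: id_a, id_b, r
        ids = sorted(set(df.iloc[:, 0].astype(str)) |
                     set(df.iloc[:, 1].astype(str)))
        pos = {v: i for i, v in enumerate(ids)}
        R = np.eye(len(ids))
        for a, b, r in df.itertuples(index=False):
            i, j = pos[str(a)], pos[str(b)]
            R[i, j] = R[j, i] = float(r)
        return LDReference(R, ids)
    try:
        R = df.to_numpy(dtype=float)
    except ValueError as e:
        raise InputError(f"{path}: non-numeric LD entry ({e})") from e
    if R.shape[0] != R.shape[1]:
        raise InputError(f"{path}: LD matrix is {R.shape[0]}x{R.shape[1]}, "
                         "expected square")
    finite = np.isfinite(R) & np.isfinite(R.T)
    if np.nanmax(np.abs(np.where(finite, R - R.T, 0.0))) > atol:
        raise InputError(f"{path}: LD matrix asymmetric beyond {atol}")
    R = np.where(finite, 0.5 * (R + R.T), R)
    try:
        return LDReference(R, cols)
    except ValueError as e:
        raise InputError(f"{path}: {e}") from e


def load_inputs(pheno_path=None, geno_path=None, sumstats_paths=(),
                ld_paths=()):
    """Assemble datasets and LD panels from files, with a validation report.

    Individual-level mode pairs one phenotype table (one column per trait)
    with one genotype table; summary mode takes one file per trait.

    Returns ``(datasets, ld_panels, report)`` where ``report`` lists
    dropped/flagged variants per trait.
    """
    datasets = []
    report = {}
    if pheno_path is not None:
        if geno_path is None:
            raise InputError("individual-level mode needs a genotype table")
        X, var_ids = read_genotypes(geno_path)
        Y, trait_ids = read_phenotypes(pheno_path)
        if Y.shape[0] != X.shape[0]:
            raise InputError(
                f"{pheno_path}: {Y.shape[0]} samples but genotype table "
                f"{geno_path} has {X.shape[0]}")
        for li, tid in enumerate(trait_ids):
            ds = TraitDataset.from_raw(tid, Y[:, li], X, var_ids)
            dropped = sorted(set(var_ids) - set(ds.variant_ids))
            report[tid] = {"dropped_constant": dropped}
            datasets.append(ds)
    for p in sumstats_paths:
        ss = read_summary_stats(p)
        report[ss.trait_id] = {"dropped_constant": []}
        datasets.append(ss)
    panels = [read_ld(p) for p in ld_paths]
    return datasets, panels, report


def events_table(result) -> pd.DataFrame:
    """Events as a flat table (one row per event)."""
    rows = []
    for ev in result.events:
        rows.append({
            "event_id": ev.event_id,
            "label": ev.label,
            "traits": ",".join(ev.traits),
            "n_variants": ev.size,
            "cos_variants": ",".join(ev.cos_ids),
            "cos_weights": ",".join(f"{w:.6g}" for w in ev.w),
            "purity": round(ev.purity, 6),
            "gain": round(ev.gain, 6),
            "coverage": ev.coverage,
            "ld_flagged": ev.ld_flagged,
        })
    cols = ["event_id", "label", "traits", "n_variants", "cos_variants",
            "cos_weights", "purity", "gain", "coverage", "ld_flagged"]
    return pd.DataFrame(rows, columns=cols)


def vcp_table(result) -> pd.DataFrame:
    return pd.DataFrame({
        "variant_id": result.variant_ids,
        "vcp": np.round(result.vcp, 6),
    })


def write_results(result, outdir, config=None, seed=None):
    """Write events, VCP scores and run metadata under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_table(result).to_csv(outdir / "events.tsv", sep="\t", index=False)
    vcp_table(result).to_csv(outdir / "vcp.tsv", sep="\t", index=False)
    cfg = config if config is not None else result.fit.config
    meta = {
        "version": _version(),
        "config": {k: v for k, v in vars(cfg).items()},
        "seed": seed,
        "n_rounds": result.fit.n_rounds,
        "traits": result.fit.trait_ids,
        "focal": result.fit.focal,
        "gated_out": [t for t, ok in result.fit.gated.items() if not ok],
    }
    (outdir / "run.json").write_text(json.dumps(meta, indent=2, default=str))
    return outdir


def write_simulation(locus, outdir):
    """Write a simulated locus: genotypes, phenotypes, truth (TSV + JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(locus.dosages, columns=locus.variant_ids).to_csv(
        outdir / "genotypes.tsv", sep="\t", index=False)
    pd.DataFrame(
        {ds.trait_id: ds.Y for ds in locus.datasets}
    ).to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    truth = locus.truth
    rows = [{"causal_variant": locus.variant_ids[int(j)],
             "causal_index": int(j),
             "traits": ",".join(cfg)}
            for j, cfg in zip(truth.causal, truth.configs)]
    pd.DataFrame(rows, columns=["causal_variant", "causal_index", "traits"]
                 ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    d = truth.to_dict()
    d["causal_variants"] = [locus.variant_ids[int(j)] for j in truth.causal]
    (outdir / "truth.json").write_text(json.dumps(d, indent=2, default=str))
    return outdir


def _version() -> str:
    from . import __version__
    return __version__
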