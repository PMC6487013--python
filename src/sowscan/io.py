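"""Readers and writers for the pipeline's on-disk formats.

Formats: pedigree CSV (animal,sire,dam; 0/blank = unknown), genotype
matrix as a PLINK-.raw-like TSV plus a .map-like TSV, phenotype TSV,
PennCNV rawcnv text, sample-metrics TSV, CNVR TSV/BED, window and effect
TSVs, YAML run configuration. Internal coordinates are 1-based inclusive;
BED output is converted to 0-based half-open at this boundary only. Every
output file starts with comment lines recording tool version, seed and a
config hash.
"""

from __future__ import annotations

import graphlib
import hashlib
import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cnvr import Cnvr
from .errors import DataError, PedigreeError
from .relationship import UNKNOWN, GenotypePanel, Pedigree
from .simulate import CnvCall, SimConfig
from .wssgwas import SnpEffects, WindowResult

_RAWCNV_RE = re.compile(
    r"^chr(?P<chrom>\w+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+length=(?P<length>[\d,]+)\s+"
    r"state(?P<state>\d+),cn=(?P<cn>\d+)\s+(?P<sample>\S+)"
)


def header_lines(seed=None, config: dict | None = None) -> list[str]:
    """Comment header recording version, seed and a config hash."""
    lines = [f"# sowscan v{__version__}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        lines.append(f"# config_sha={digest}")
    return lines


def _write_with_header(df: pd.DataFrame, path, sep="\t", seed=None, config=None):
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines(seed, config):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False)


def _read_table(path, sep="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------- pedigree

def write_pedigree(pedigree: Pedigree, path, **meta):
    def lab(pos):
        return 0 if pos == UNKNOWN else pedigree.ids[pos]

    df = pd.DataFrame(
        {
            "animal": pedigree.ids,
            "sire": [lab(s) for s in pedigree.sire],
            "dam": [lab(d) for d in pedigree.dam],
        }
    )
    if pedigree.sex is not None:
        df["sex"] = np.where(pedigree.sex == 1, "F", "M")
    _write_with_header(df, path, sep=",", **meta)


def read_pedigree(path) -> Pedigree:
    """Pedigree CSV with columns animal,sire,dam (0/blank = unknown).

    Rows may be in any order; a topological sort is applied. Duplicate ids,
    self-parenting and cycles are rejected with the offending line.
    """
    df = _read_table(path, sep=",")
    for col in ("animal", "sire", "dam"):
        if col not in df.columns:
            raise PedigreeError(f"pedigree file missing column {col!r}")
    animals = df["animal"].tolist()
    seen = {}
    for lineno, a in enumerate(animals, start=2):
        if a in seen:
            raise PedigreeError(f"duplicate animal id {a!r} at line {lineno}")
        seen[a] = lineno

    def parent(v):
        if pd.isna(v) or v == 0 or v == "0" or v == "":
            return None
        return v

    graph = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        s, d = parent(row.sire), parent(row.dam)
        if s == row.animal or d == row.animal:
            raise PedigreeError(
                f"animal {row.animal!r} listed as its own parent at line {lineno}"
            )
        graph[row.animal] = [p for p in (s, d) if p is not None]
    # parents that never appear as animals become implicit founders
    implicit = {p for ps in graph.values() for p in ps if p not in graph}
    for p in implicit:
        graph[p] = []
    file_order = sorted(implicit, key=str) + animals
    seen_so_far: set = set()
    already_sorted = True
    for a in file_order:
        if any(p not in seen_so_far for p in graph[a]):
            already_sorted = False
            break
        seen_so_far.add(a)
    if already_sorted:
        order = file_order  # keep the user's ordering when it is valid
    else:
        try:
            order = list(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as exc:
            raise PedigreeError(f"pedigree contains a cycle: {exc.args[1]}") from exc
    pos = {a: i for i, a in enumerate(order)}
    parents = {row.animal: (parent(row.sire), parent(row.dam)) for row in df.itertuples(index=False)}
    sex_col = None
    if "sex" in df.columns:
        sex_map = dict(zip(df["animal"], df["sex"]))
        sex_col = np.array(
            [1 if str(sex_map.get(a, "")).upper().startswith("F") else 0 for a in order]
        )
    sire = np.array(
        [pos[parents.get(a, (None, None))[0]] if parents.get(a, (None, None))[0] is not None else UNKNOWN for a in order]
    )
    dam = np.array(
        [pos[parents.get(a, (None, None))[1]] if parents.get(a, (None, None))[1] is not None else UNKNOWN for a in order]
    )
    return Pedigree(ids=np.array(order), sire=sire, dam=dam, sex=sex_col)


# ---------------------------------------------------------------- genotypes

def write_genotypes(panel: GenotypePanel, raw_path, map_path, **meta):
    geno = pd.DataFrame(panel.genotypes, columns=panel.snp_ids)
    geno.insert(0, "sample_id", panel.sample_ids)
    _write_with_header(geno, raw_path, **meta)
    snp_map = pd.DataFrame(
        {"chrom": panel.chrom, "snp_id": panel.snp_ids, "pos_bp": panel.pos_bp}
    )
    _write_with_header(snp_map, map_path, **meta)


def read_genotypes(raw_path, map_path, pedigree: Pedigree) -> GenotypePanel:
    geno = _read_table(raw_path)
    snp_map = _read_table(map_path)
    sample_ids = geno["sample_id"].to_numpy()
    matrix = geno.drop(columns="sample_id").to_numpy(dtype=np.int8)
    if not set(np.unique(matrix)) <= {0, 1, 2}:
        raise DataError("genotypes must be coded 0/1/2")
    return GenotypePanel(
        sample_ids=sample_ids,
        sample_pos=pedigree.position_of(sample_ids),
        genotypes=matrix,
        snp_ids=snp_map["snp_id"].to_numpy(),
        chrom=snp_map["chrom"].to_numpy(),
        pos_bp=snp_map["pos_bp"].to_numpy(),
    )


# ---------------------------------------------------------------- phenotypes

def write_phenotypes(table: pd.DataFrame, path, **meta):
    _write_with_header(table, path, **meta)


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = {"animal", "cg", "value"} - set(df.columns)
    if missing:
        raise DataError(f"phenotype file missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------- CNV calls

def write_rawcnv(calls: list[CnvCall], path, **meta):
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines(**meta):
            fh.write(line + "\n")
        for c in calls:
            state = 2 if c.state == "loss" else 5
            fh.write(
                f"chr{c.chrom}:{c.start_bp}-{c.end_bp} numsnp={c.num_snps} "
                f"length={c.length_bp} state{state},cn={c.copy_number} {c.sample_id}\n"
            )


def read_rawcnv(path) -> list[CnvCall]:
    """PennCNV rawcnv-style lines → CnvCall list (1-based inclusive).

    cn < 2 maps to loss, cn > 2 to gain; cn = 2 lines are rejected. A
    length field inconsistent with end − start + 1 draws a warning and the
    coordinates win.
    """
    calls = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            m = _RAWCNV_RE.match(line)
            if not m:
                raise DataError(f"malformed rawcnv line {lineno}: {line!r}")
            cn = int(m["cn"])
            if cn == 2:
                raise DataError(
                    f"line {lineno}: cn=2 is not a copy-number variant call"
                )
            start, end = int(m["start"]), int(m["end"])
            stated = int(m["length"].replace(",", ""))
            if stated != end - start + 1:
                warnings.warn(
                    f"line {lineno}: length field {stated} inconsistent with "
                    f"coordinates ({end - start + 1}); coordinates win"
                )
            calls.append(
                CnvCall(
                    sample_id=m["sample"],
                    chrom=int(m["chrom"]),
                    start_bp=start,
                    end_bp=end,
                    state="loss" if cn < 2 else "gain",
                    copy_number=cn,
                    num_snps=int(m["numsnp"]),
                )
            )
    return calls


def read_sample_metrics(path) -> pd.DataFrame:
    df = _read_table(path)
    if "sample_id" not in df.columns:
        raise DataError("sample metrics file must have a sample_id column")
    return df


# ---------------------------------------------------------------- results

def write_cnvrs(cnvrs: list[Cnvr], tsv_path, bed_path=None, **meta):
    cols = ["chrom", "start_bp", "end_bp", "length_bp", "state", "n_carriers",
            "frequency", "recurrence"]
    df = pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_bp": r.length_bp,
                "state": r.state,
                "n_carriers": r.n_carriers,
                "frequency": r.frequency,
                "recurrence": r.recurrence,
            }
            for r in cnvrs
        ],
        columns=cols,
    )
    _write_with_header(df, tsv_path, **meta)
    if bed_path is not None:
        with Path(bed_path).open("w") as fh:
            for r in cnvrs:
                # BED: 0-based half-open
                fh.write(
                    f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{r.state}\t{r.n_carriers}\n"
                )


def write_windows(windows: list[WindowResult], path, **meta):
    df = pd.DataFrame(
        [
            {
                "chrom": w.chrom,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "n_snps": w.n_snps,
                "pct_variance": w.pct_variance,
            }
            for w in windows
        ]
    )
    _write_with_header(df, path, **meta)


def write_snp_effects(
    effects: list[SnpEffects], panel: GenotypePanel, path, **meta
):
    frames = []
    for e in effects:
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": panel.snp_ids,
                    "chrom": panel.chrom,
                    "pos_bp": panel.pos_bp,
                    "u_hat": e.u_hat,
                    "weight": e.d,
                    "iteration": e.iteration,
                }
            )
        )
    _write_with_header(pd.concat(frames, ignore_index=True), path, **meta)


def write_solutions(solution, model, path, **meta):
    """Solutions TSV: one row per effect level (cg, animal, pe)."""
    rows = []
    cg = model.cg_labels if model.cg_labels is not None else range(len(solution.b_hat))
    for label, est in zip(cg, solution.b_hat):
        rows.append(("cg", label, est))
    animals = model.animal_labels if model.animal_labels is not None else range(len(solution.a_hat))
    for label, est in zip(animals, solution.a_hat):
        rows.append(("animal", label, est))
    pe_labels = model.pe_labels if model.pe_labels is not None else range(len(solution.pe_hat))
    for label, est in zip(pe_labels, solution.pe_hat):
        rows.append(("pe", label, est))
    df = pd.DataFrame(rows, columns=["effect", "level", "estimate"])
    _write_with_header(df, path, **meta)


def read_gene_bed(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open → 1-based inclusive)."""
    rows = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"BED line {lineno} has fewer than 3 columns")
            chrom = parts[0].removeprefix("chr")
            name = parts[3] if len(parts) > 3 else f"feature{lineno}"
            rows.append((int(chrom), int(parts[1]) + 1, int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])


def write_matrix_coo(matrix, path, tol: float = 0.0, **meta):
    """Coordinate-format text (row, col, value) for inspection."""
    import scipy.sparse as sp

    coo = sp.coo_matrix(matrix)
    df = pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data})
    if tol > 0:
        df = df[np.abs(df["value"]) > tol]
    _write_with_header(df, path, **meta)


# ---------------------------------------------------------------- config

def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise DataError("run configuration must be a YAML mapping")
    return cfg


def sim_config_from_dict(cfg: dict) -> SimConfig:
    known = {f for f in SimConfig.__dataclass_fields__}
    sim = {k: v for k, v in cfg.get("simulate", {}).items() if k in known}
    for key in ("maf_range", "records_per_sow_range", "cnv_carrier_freq_range"):
        if key in sim and isinstance(sim[key], list):
            sim[key] = tuple(sim[key])
    if "seed" in cfg and "seed" not in sim:
        sim["seed"] = cfg["seed"]
    return SimConfig(**sim)
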