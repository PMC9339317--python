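"""Text-format exchange: GRM triplets, genotype/phenotype tables, configs.

The GRM is exchanged in the GCTA text convention: a ``.grm(.gz)`` file of
whitespace-separated lower-triangle triplets ``i j M value`` with 1-based
indices and the marker count per pair, alongside a ``.grm.id`` file of
``FID IID`` rows.  Genotypes are exchanged as PLINK ``.raw``-style text
(header ``FID IID PAT MAT SEX PHENOTYPE`` then one allele-count column per
marker) with a YAML sidecar for allele frequencies and the causal mask, or
as plain CSV; phenotypes as three-column PLINK ``.phen``.  Text formats were
chosen over the binary originals for auditability.
"""

from __future__ import annotations

import gzip
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import simdata
from .estimators import GRMatrix

__all__ = [
    "write_grm",
    "read_grm",
    "write_phen",
    "read_phen",
    "write_genotypes",
    "read_genotypes",
    "spec_to_dict",
    "spec_from_dict",
    "load_config",
    "dump_config",
]

_RAW_LEAD = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _opener(path: Path):
    return gzip.open if path.suffix == ".gz" else open


def write_grm(grm: GRMatrix, ids, prefix: str, gz: bool = True) -> tuple[Path, Path]:
    """Write a GRM as GCTA text triplets plus an id file.

    Returns the (triplet, id) paths.  Values are written with 8 significant
    digits; the lower triangle including the diagonal is stored row-major.
    """
    ids = list(ids)
    n = grm.psi.shape[0]
    if len(ids) != n:
        raise ValueError("id count does not match GRM size")
    if len(set(ids)) != n:
        raise ValueError("ids must be unique")
    prefix_p = Path(prefix)
    grm_path = prefix_p.with_suffix(prefix_p.suffix + (".grm.gz" if gz else ".grm"))
    id_path = prefix_p.with_suffix(prefix_p.suffix + ".grm.id")
    op = _opener(grm_path)
    with op(grm_path, "wt") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{grm.M_used}\t{grm.psi[i, j]:.8g}\n")
    with open(id_path, "w") as fh:
        for iid in ids:
            fh.write(f"{iid}\t{iid}\n")
    return grm_path, id_path


def read_grm(prefix: str) -> tuple[GRMatrix, list]:
    """Read a GCTA text GRM written by :func:`write_grm` (or compatible)."""
    prefix_p = Path(prefix)
    id_path = prefix_p.with_suffix(prefix_p.suffix + ".grm.id")
    grm_path = None
    for suff in (".grm.gz", ".grm"):
        cand = prefix_p.with_suffix(prefix_p.suffix + suff)
        if cand.exists():
            grm_path = cand
            break
    if grm_path is None:
        raise FileNotFoundError(f"no .grm(.gz) file for prefix {prefix}")
    if not id_path.exists():
        raise FileNotFoundError(f"missing id file {id_path}")
    ids = [line.split()[1] for line in id_path.read_text().splitlines() if line.strip()]
    n = len(ids)
    psi = np.zeros((n, n))
    m_used = 0
    expected = n * (n + 1) // 2
    count = 0
    op = _opener(grm_path)
    with op(grm_path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{grm_path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                i, j = int(parts[0]) - 1, int(parts[1]) - 1
                m_used = int(parts[2])
                val = float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{grm_path}:{lineno}: unparseable triplet") from exc
            if not (0 <= j <= i < n):
                raise ValueError(f"{grm_path}:{lineno}: index ({i + 1},{j + 1}) out of range")
            psi[i, j] = psi[j, i] = val
            count += 1
    if count != expected:
        raise ValueError(
            f"{grm_path}: truncated or malformed file: {count} triplets, expected {expected}"
        )
    return GRMatrix(psi=psi, M_used=m_used), ids


def write_phen(y: np.ndarray, ids, path: str) -> Path:
    """Write a PLINK .phen file (FID IID value)."""
    path_p = Path(path)
    with open(path_p, "w") as fh:
        for iid, val in zip(ids, y, strict=True):
            fh.write(f"{iid}\t{iid}\t{val:.10g}\n")
    return path_p


def read_phen(path: str) -> tuple[np.ndarray, list]:
    vals, ids = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
        ids.append(parts[1])
        vals.append(float(parts[2]))
    return np.asarray(vals), ids


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.yaml")


def write_genotypes(
    data: simdata.GenotypeData, path: str, dialect: str = "raw"
) -> Path:
    """Write integer genotypes as PLINK .raw-style text or plain CSV.

    A YAML sidecar stores allele frequencies, the causal mask, and the
    backend.  Continuous (gaussian-backend) genotypes are refused: the raw
    dialect is defined on allele counts.
    """
    if dialect not in ("raw", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if data.backend == "gaussian" or not np.issubdtype(data.G.dtype, np.integer):
        raise ValueError("raw/csv dialects require integer allele counts")
    path_p = Path(path)
    n, M = data.G.shape
    snp_names = [f"snp{j + 1}" for j in range(M)]
    with open(path_p, "w") as fh:
        if dialect == "raw":
            fh.write(" ".join(_RAW_LEAD + snp_names) + "\n")
            for i in range(n):
                row = [f"ind{i + 1}", f"ind{i + 1}", "0", "0", "0", "-9"]
                fh.write(" ".join(row + [str(int(g)) for g in data.G[i]]) + "\n")
        else:
            fh.write(",".join(["id"] + snp_names) + "\n")
            for i in range(n):
                fh.write(",".join([f"ind{i + 1}"] + [str(int(g)) for g in data.G[i]]) + "\n")
    meta = {
        "backend": data.backend,
        "causal_mask": [bool(b) for b in data.causal_mask],
        "freqs": None if data.freqs is None else [float(p) for p in data.freqs.freqs],
        "seed_record": {k: str(v) for k, v in data.seed_record.items()},
    }
    _sidecar_path(path_p).write_text(yaml.safe_dump(meta))
    return path_p


def read_genotypes(path: str, dialect: str = "raw") -> simdata.GenotypeData:
    """Read genotypes written by :func:`write_genotypes`.

    If the sidecar is missing, genotypes still load; the causal mask is then
    reported absent (all-False) and frequencies are ``None``.
    """
    path_p = Path(path)
    lines = [ln for ln in path_p.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty genotype file")
    if dialect == "raw":
        header = lines[0].split()
        if header[: len(_RAW_LEAD)] != _RAW_LEAD:
            raise ValueError(f"{path}: not a .raw header")
        M = len(header) - len(_RAW_LEAD)
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            parts = line.split()
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: {len(parts)} fields, header has {len(header)}"
                )
            rows.append([int(v) for v in parts[len(_RAW_LEAD):]])
    elif dialect == "csv":
        header = lines[0].split(",")
        M = len(header) - 1
        rows = []
        for lineno, line in enumerate(lines[1:], start=2):
            parts = line.split(",")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: {len(parts)} fields, header has {len(header)}"
                )
            rows.append([int(v) for v in parts[1:]])
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    G = np.asarray(rows, dtype=np.int8)

    sidecar = _sidecar_path(path_p)
    freqs = None
    mask = np.zeros(M, dtype=bool)
    backend = "binomial_threshold"
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        if meta.get("freqs") is not None:
            freqs = simdata.AlleleFrequencySet(np.asarray(meta["freqs"]))
        if meta.get("causal_mask") is not None:
            mask = np.asarray(meta["causal_mask"], dtype=bool)
        backend = meta.get("backend", backend)
    return simdata.GenotypeData(
        G=G, freqs=freqs, causal_mask=mask, backend=backend,
        seed_record={"source": str(path_p)},
    )


# ---------------------------------------------------------------------------
# structured configuration
# ---------------------------------------------------------------------------


def spec_to_dict(spec: simdata.LDStructureSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> simdata.LDStructureSpec:
    return simdata.LDStructureSpec(**d)


def dump_config(config: dict, path: str) -> Path:
    """Write a run configuration as YAML; round-trips losslessly."""
    path_p = Path(path)
    payload = dict(config)
    if isinstance(payload.get("ld_spec"), simdata.LDStructureSpec):
        payload["ld_spec"] = spec_to_dict(payload["ld_spec"])
    path_p.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path_p


def load_config(path: str) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    if isinstance(config.get("ld_spec"), dict):
        config["ld_spec"] = spec_from_dict(config["ld_spec"])
    return config
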