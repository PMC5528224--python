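"""Table and config I/O plus run manifests.

All tables are plain CSV with a header; the required ``used`` column is
0/1, an optional ``stratum`` column marks case-control strata, and the
remaining columns are numeric covariates.  Configs, model specs and
manifests use a flat ``key = value`` text format so that every artifact
on disk is reproducible from its manifest.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .errors import InputError
from .fitting import FitResult, UsedAvailableTable, summary_table

__all__ = [
    "load_table",
    "save_table",
    "read_kv",
    "write_kv",
    "sha256_file",
    "write_manifest",
    "write_fit_result",
]


def load_table(path) -> UsedAvailableTable:
    """Read a used-available CSV into a validated table."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InputError(f"empty table file: {path}") from None
    except Exception as exc:  # malformed CSV
        raise InputError(f"cannot parse {path}: {exc}") from None
    if len(df) == 0:
        raise InputError(f"table {path} has a header but no rows")
    table = UsedAvailableTable(df)
    if table.has_strata:
        table.validate_strata()
    return table


def save_table(table: UsedAvailableTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_kv(path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file (later keys win; ``#``
    starts a comment line)."""
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            if not sep:
                raise InputError(f"{path} line {lineno}: expected 'key = value'")
            out[key.strip()] = value.strip()
    return out


def write_kv(mapping: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in mapping.items():
            fh.write(f"{key} = {value}\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir, command: str, options: dict, inputs: dict) -> Path:
    """Echo the full run configuration (all defaults included) plus input
    checksums so the run can be reproduced exactly."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {
        "command": command,
        "selstrength_version": __version__,
    }
    for key, value in sorted(options.items()):
        manifest[f"option.{key}"] = str(value)
    for key, value in sorted(inputs.items()):
        manifest[f"input.{key}"] = str(value)
        p = Path(value)
        if p.exists() and p.is_file():
            manifest[f"sha256.{key}"] = sha256_file(p)
    path = outdir / "manifest.txt"
    write_kv(manifest, path)
    return path


def write_fit_result(fit: FitResult, outdir) -> None:
    """Serialise a fit as key-value text plus a CSV summary table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kv: dict[str, str] = {
        "estimator": fit.estimator,
        "form": fit.model.form,
        "converged": str(fit.converged).lower(),
        "iterations": fit.iterations,
        "loglik": repr(fit.loglik),
        "aic": repr(fit.aic),
        "n_used": fit.n_used,
        "n_avail": fit.n_avail,
    }
    for name, est, se in zip(fit.param_names, fit.params, fit.se):
        kv[f"estimate.{name}"] = repr(float(est))
        kv[f"se.{name}"] = repr(float(se))
    if fit.model.intercept is not None and not fit.intercept_identifiable:
        kv["intercept.nonidentifiable"] = repr(float(fit.model.intercept))
        if fit.intercept_se is not None:
            kv["intercept.se"] = repr(float(fit.intercept_se))
    for i, msg in enumerate(fit.warnings):
        kv[f"warning.{i}"] = msg
    write_kv(kv, outdir / "fit.txt")
    if fit.converged:
        summary_table(fit).to_csv(outdir / "summary.csv", index=False)
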