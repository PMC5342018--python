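"""Plain-text readers and writers (TSV, GMT, JSON) for every pipeline stage."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

from .errors import InputError
from .preprocess import ExpressionBundle, FactorInput
from .signature import Signature


# -- expression bundles -----------------------------------------------------

def write_bundle(bundle: ExpressionBundle, outdir: str | Path,
                 prefix: str = "expression") -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "values": outdir / f"{prefix}.tsv",
        "meta": outdir / f"{prefix}_samples.tsv",
    }
    bundle.values.rename_axis("feature").to_csv(paths["values"], sep="\t")
    bundle.sample_meta.rename_axis("sample_id").to_csv(paths["meta"], sep="\t")
    if bundle.probe_map is not None:
        paths["probe_map"] = outdir / f"{prefix}_probes.tsv"
        bundle.probe_map.rename_axis("probe").rename("gene").to_csv(
            paths["probe_map"], sep="\t")
    return paths


def read_bundle(values_path: str | Path, meta_path: str | Path,
                probe_map_path: str | Path | None = None) -> ExpressionBundle:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    probe_map = None
    if probe_map_path is not None:
        probe_map = pd.read_csv(probe_map_path, sep="\t", index_col=0)["gene"]
    return ExpressionBundle(values=values, sample_meta=meta, probe_map=probe_map)


# -- factor input -----------------------------------------------------------

def write_factor_input(fi: FactorInput, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"D": outdir / "D.tsv", "Sigma": outdir / "Sigma.tsv",
             "conditions": outdir / "conditions.tsv"}
    fi.D.rename_axis("gene").to_csv(paths["D"], sep="\t")
    fi.Sigma.rename_axis("gene").to_csv(paths["Sigma"], sep="\t")
    fi.condition_meta.rename_axis("condition").to_csv(paths["conditions"], sep="\t")
    return paths


def read_factor_input(indir: str | Path) -> FactorInput:
    indir = Path(indir)
    D = pd.read_csv(indir / "D.tsv", sep="\t", index_col=0)
    Sigma = pd.read_csv(indir / "Sigma.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(indir / "conditions.tsv", sep="\t", index_col=0)
    return FactorInput(D=D, Sigma=Sigma, condition_meta=meta)


# -- gene sets --------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene sets as name -> set of gene labels."""
    return {name: set(genes) for name, genes in _gseapy_read_gmt(str(path)).items()}


def write_gmt(gene_sets: dict[str, set[str]], path: str | Path,
              description: str = "na") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(gene_sets):
            genes = "\t".join(sorted(gene_sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")
    return path


# -- survival ---------------------------------------------------------------

def write_survival(survival: pd.Series, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    survival.rename("relative_survival").reset_index().to_csv(path, sep="\t", index=False)
    return path


def read_survival(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    required = {"background", "treatment", "relative_survival"}
    if not required <= set(df.columns):
        raise InputError(f"survival table needs columns {sorted(required)}")
    return df.set_index(["background", "treatment"])["relative_survival"]


# -- alterations ------------------------------------------------------------

def write_alterations(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)
    return path


def read_alterations(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    table["mutated"] = table["mutated"].astype(bool)
    table["gistic"] = table["gistic"].astype(int)
    return table


# -- signatures and JSON artifacts -----------------------------------------

def write_signature(sig: Signature, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"reference": sig.reference_gene,
               "up": sorted(sig.up), "down": sorted(sig.down)}
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path


def read_signature(path: str | Path) -> Signature:
    payload = json.loads(Path(path).read_text())
    return Signature(reference_gene=payload["reference"],
                     up=set(payload["up"]), down=set(payload["down"]))


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable) + "\n")
    return path


def _jsonable(obj):
    try:
        import numpy as np
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
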