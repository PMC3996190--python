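"""Readers, writers, configuration and run manifests.

Tabular interchange is CSV (RFC-4180, UTF-8) with the exact header
``eye_id,subject_id,group,scan_index,layer,region,TH_um,TR,FD``; reports are
JSON; configuration is YAML.  Synthetic B-scans are written as 16-bit
grayscale PNG with a JSON sidecar carrying boundaries and pixel pitches.
Every pipeline output directory receives a run manifest (config echo, seeds,
file hashes, timestamps) from which the outputs can be regenerated.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import pathlib

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enums import FEATURE_COLUMNS, GroupLabel, LayerName, RegionName
from .errors import OctbandError, ValidationError
from .protocol import TestConfig, TestId
from .synthetic_cohort import CohortSpec, SyntheticScan, default_feature_params

_VALID = {
    "group": {g.value for g in GroupLabel},
    "layer": {l.value for l in LayerName},
    "region": {r.value for r in RegionName},
}


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table with the canonical column order.

    Extra working columns (e.g. provenance flags) are dropped; missing
    canonical columns are an error.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"write_feature_table: missing columns {missing}")
    table[list(FEATURE_COLUMNS)].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read and validate a feature-table CSV.

    The header must match the canonical schema exactly (unknown columns are
    rejected by name); categorical strings are validated against the group /
    layer / region vocabularies and failures name the offending data row.
    """
    table = pd.read_csv(
        path, dtype={"eye_id": str, "subject_id": str}, keep_default_na=False
    )
    unknown = [c for c in table.columns if c not in FEATURE_COLUMNS]
    if unknown:
        raise ValidationError(f"read_feature_table: unknown columns {unknown}")
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"read_feature_table: missing columns {missing}")
    for col, valid in _VALID.items():
        bad = ~table[col].isin(valid)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"read_feature_table: invalid {col} {table[col].iloc[row]!r} "
                f"in data row {row}"
            )
    if len(table):
        if (table["TH_um"].to_numpy() <= 0).any():
            raise ValidationError("read_feature_table: TH_um must be > 0")
        if (table["TR"].to_numpy() < 0).any():
            raise ValidationError("read_feature_table: TR must be >= 0")
        fd = table["FD"].to_numpy()
        if ((fd < 1.0) | (fd > 2.0)).any():
            raise ValidationError("read_feature_table: FD must lie in [1, 2]")
        dup = table.duplicated(["eye_id", "scan_index", "layer", "region"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            raise ValidationError(
                f"read_feature_table: duplicate (eye, scan, layer, region) key "
                f"in data row {row}"
            )
    table["scan_index"] = table["scan_index"].astype(np.int64)
    return table


# --------------------------------------------------------------------------
# Synthetic scan I/O
# --------------------------------------------------------------------------


def write_scan(scan: SyntheticScan, png_path) -> None:
    """16-bit grayscale PNG plus a ``<stem>.json`` sidecar."""
    import imageio.v3 as iio

    png_path = pathlib.Path(png_path)
    iio.imwrite(png_path, np.round(scan.image * 65535).astype(np.uint16))
    sidecar = {
        "boundaries_um": scan.boundaries.tolist(),
        "lateral_pitch_um": scan.lateral_pitch_um,
        "axial_pitch_um": scan.axial_pitch_um,
        "eye_id": scan.eye_id,
        "scan_index": scan.scan_index,
        "group": scan.group,
        "subject_id": scan.subject_id,
    }
    png_path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_scan(png_path) -> SyntheticScan:
    import imageio.v3 as iio

    png_path = pathlib.Path(png_path)
    image = iio.imread(png_path).astype(float) / 65535.0
    meta = json.loads(png_path.with_suffix(".json").read_text())
    return SyntheticScan(
        image=image,
        boundaries=np.asarray(meta["boundaries_um"], dtype=float),
        lateral_pitch_um=meta["lateral_pitch_um"],
        axial_pitch_um=meta["axial_pitch_um"],
        eye_id=meta["eye_id"],
        scan_index=meta["scan_index"],
        group=meta.get("group"),
        subject_id=meta.get("subject_id"),
    )


# --------------------------------------------------------------------------
# YAML configuration
# --------------------------------------------------------------------------


def _cohort_from_dict(raw: dict, errors: list[str]) -> CohortSpec | None:
    spec = CohortSpec()
    try:
        if "n_eyes_per_group" in raw:
            spec.n_eyes_per_group = {
                GroupLabel(k.upper()): int(v)
                for k, v in raw["n_eyes_per_group"].items()
            }
        for key in ("scans_per_eye", "rho", "rng_seed"):
            if key in raw:
                setattr(spec, key, raw[key])
        if "scan_noise_sd" in raw:
            spec.scan_noise_sd = {str(k): float(v) for k, v in raw["scan_noise_sd"].items()}
        if "regions" in raw:
            spec.regions = tuple(RegionName(r.upper()) for r in raw["regions"])
        if "feature_params" in raw:
            params = default_feature_params()
            for g, layers in raw["feature_params"].items():
                for l, feats in layers.items():
                    for f, pair in feats.items():
                        params[GroupLabel(g.upper())][LayerName(l.upper())][f] = tuple(pair)
            spec.feature_params = params
        spec.validate()
        return spec
    except (ValidationError, ValueError, KeyError, TypeError) as exc:
        errors.append(f"cohort: {exc}")
        return None


def _test_from_dict(raw: dict, errors: list[str]) -> TestConfig | None:
    try:
        kwargs: dict = {}
        if "test_id" in raw:
            t = str(raw["test_id"]).upper()
            kwargs["test_id"] = TestId(t if t.startswith("TEST") else f"TEST{t}")
        if "reference_group" in raw:
            kwargs["reference_group"] = GroupLabel(raw["reference_group"].upper())
        if "contrast_groups" in raw:
            kwargs["contrast_groups"] = tuple(
                GroupLabel(g.upper()) for g in raw["contrast_groups"]
            )
        if "layers" in raw:
            kwargs["layers"] = tuple(LayerName(l.upper()) for l in raw["layers"])
        if "input_features" in raw:
            kwargs["input_features"] = tuple(
                f.upper() for f in raw["input_features"]
            )
        if "region" in raw:
            kwargs["region"] = RegionName(raw["region"].upper())
        for key in (
            "n_train", "target_feature", "c", "coverage", "rng_seed",
            "n_repeats",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        if "train_sizes" in raw:
            kwargs["train_sizes"] = tuple(int(s) for s in raw["train_sizes"])
        if "mcmc" in raw:
            from .brbf import BRBFConfig

            kwargs["brbf_config"] = BRBFConfig(**raw["mcmc"])
        cfg = TestConfig(**kwargs)
        cfg.validate()
        return cfg
    except (ValidationError, ValueError, KeyError, TypeError) as exc:
        errors.append(f"test: {exc}")
        return None


def load_config(path) -> dict:
    """Load a YAML config with optional ``cohort`` and ``test`` sections.

    Defaults are resolved; all validation errors are aggregated and reported
    together.  Additionally rejects a training-set size exceeding the
    configured reference-group size.
    """
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config: top level must be a mapping")
    errors: list[str] = []
    bundle = {
        "cohort": _cohort_from_dict(raw.get("cohort", {}) or {}, errors),
        "test": _test_from_dict(raw.get("test", {}) or {}, errors),
    }
    if "test" in raw and bundle["cohort"] is not None and bundle["test"] is not None:
        cfg = bundle["test"]
        n_ref = bundle["cohort"].n_eyes_per_group.get(cfg.reference_group, 0)
        max_train = (
            max(cfg.train_sizes) if cfg.test_id is TestId.TEST2 else cfg.n_train
        )
        if max_train >= n_ref:
            errors.append(
                f"test: n_train {max_train} must be smaller than the "
                f"{cfg.reference_group.value} group size {n_ref}"
            )
    if errors:
        raise ValidationError("; ".join(errors))
    return bundle


def dump_config(bundle: dict) -> str:
    """YAML echo of a resolved config bundle (idempotent under load)."""
    out: dict = {}
    cohort: CohortSpec | None = bundle.get("cohort")
    if cohort is not None:
        out["cohort"] = {
            "n_eyes_per_group": {
                g.value: int(n) for g, n in cohort.n_eyes_per_group.items()
            },
            "scans_per_eye": cohort.scans_per_eye,
            "rho": cohort.rho,
            "scan_noise_sd": dict(cohort.scan_noise_sd),
            "regions": [r.value for r in cohort.regions],
            "rng_seed": cohort.rng_seed,
            "feature_params": {
                g.value: {
                    l.value: {f: list(map(float, pair)) for f, pair in feats.items()}
                    for l, feats in layers.items()
                }
                for g, layers in cohort.feature_params.items()
            },
        }
    cfg: TestConfig | None = bundle.get("test")
    if cfg is not None:
        out["test"] = {
            "test_id": cfg.test_id.value,
            "reference_group": cfg.reference_group.value,
            "contrast_groups": [g.value for g in cfg.contrast_groups],
            "n_train": cfg.n_train,
            "layers": [l.value for l in cfg.layers],
            "input_features": list(cfg.input_features),
            "target_feature": cfg.target_feature,
            "region": cfg.region.value,
            "c": cfg.band_c,
            "rng_seed": cfg.rng_seed,
            "n_repeats": cfg.n_repeats,
            "train_sizes": list(cfg.train_sizes),
            "mcmc": dataclasses.asdict(cfg.brbf_config),
        }
    return yaml.safe_dump(out, sort_keys=True)


# --------------------------------------------------------------------------
# Run manifest
# --------------------------------------------------------------------------


def _sha256(path: pathlib.Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(out_dir, config_echo: str, seeds: dict, files: list) -> pathlib.Path:
    """Write ``manifest.json`` into ``out_dir`` hashing the listed files."""
    out_dir = pathlib.Path(out_dir)
    manifest = {
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "seeds": seeds,
        "config": config_echo,
        "files": {
            str(pathlib.Path(f).name): _sha256(pathlib.Path(f)) for f in files
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def verify_manifest(out_dir) -> bool:
    """Re-hash the files listed in ``manifest.json``; True iff all match."""
    out_dir = pathlib.Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        target = out_dir / name
        if not target.exists() or _sha256(target) != digest:
            return False
    return True
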