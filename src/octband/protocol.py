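"""The three classification experiments and their diagnostic metrics.

Test 1 trains the Bayesian RBF regressor on 20 randomly selected healthy eyes
and classifies the remaining 54 healthy and all 43 MDR eyes; Test 2 repeats
Test 1 with nested training sets of 20, 30 and 40 healthy eyes; Test 3 trains
on 20 MDR eyes and classifies the remaining 23 MDR and all 38 DM eyes.  In
Tests 1 and 2 the positive condition is "healthy", in Test 3 it is "MDR"; in
every test the positive condition coincides with the reference (training)
group, and a positive test result means the discordance band classified the
eye as belonging to the reference class.

Decisions are made per eye: the six radial scans of an eye are averaged into
one feature vector before fitting and classification, and the eye's label is
attributed to all six scans, so scan-level counts are exactly six times the
eye-level counts.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import brbf, discordance
from .enums import GroupLabel, LayerName, RegionName
from .errors import OctbandError, ValidationError

SCANS_PER_EYE = 6
_UNDEFINED = "undefined"


class TestId(str, enum.Enum):
    TEST1 = "TEST1"
    TEST2 = "TEST2"
    TEST3 = "TEST3"


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    """Eye-level confusion counts; scan counts are 6x each."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        for name in ("tp", "fn", "tn", "fp"):
            if getattr(self, name) < 0:
                raise ValidationError(f"ConfusionCounts.{name}: negative count")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def scans(self) -> dict[str, int]:
        return {k: v * SCANS_PER_EYE for k, v in self.to_dict().items()}

    def to_dict(self) -> dict[str, int]:
        return {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp}


def scan_counts(eye_counts: ConfusionCounts | int, scans_per_eye: int = SCANS_PER_EYE):
    """Scan-level counts: each eye contributes ``scans_per_eye`` scans."""
    if isinstance(eye_counts, ConfusionCounts):
        return {k: v * scans_per_eye for k, v in eye_counts.to_dict().items()}
    if eye_counts < 0:
        raise ValidationError("scan_counts: negative eye count")
    return eye_counts * scans_per_eye


def confusion_metrics(counts: ConfusionCounts) -> dict:
    """Sensitivity, specificity, PPV and percent correct from counts.

    Ratios with a zero denominator are reported as the string ``"undefined"``
    together with an ``undefined`` flag listing them, never as 0.
    """
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return _UNDEFINED
        return num / den

    out = {
        "sensitivity": ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        "specificity": ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        "ppv": ratio(counts.tp, counts.tp + counts.fp, "ppv"),
        "percent_correct": (
            ratio(100.0 * (counts.tp + counts.tn), counts.total, "percent_correct")
        ),
    }
    out["undefined"] = undefined
    return out


@dataclasses.dataclass
class TestConfig:
    """Configuration of one classification experiment.

    ``input_features`` selects the regressor inputs (("TH",), ("TR",) or
    ("TH", "TR")); the target defaults to FD.  ``c`` sets the band multiplier
    directly; ``coverage`` sets it through the Gaussian error function
    (exactly one may be given; default c = 1.65).
    """

    test_id: TestId = TestId.TEST1
    reference_group: GroupLabel | None = None
    contrast_groups: tuple[GroupLabel, ...] | None = None
    n_train: int = 20
    layers: tuple[LayerName, ...] = tuple(LayerName)
    input_features: tuple[str, ...] = ("TH",)
    target_feature: str = "FD"
    region: RegionName = RegionName.PARAFOVEA
    c: float | None = None
    coverage: float | None = None
    rng_seed: int = 0
    n_repeats: int = 1
    train_sizes: tuple[int, ...] = (20, 30, 40)  # Test 2 only
    brbf_config: brbf.BRBFConfig = dataclasses.field(default_factory=brbf.BRBFConfig)

    def __post_init__(self):
        if self.reference_group is None:
            self.reference_group = (
                GroupLabel.MDR if self.test_id is TestId.TEST3 else GroupLabel.HEALTHY
            )
        if self.contrast_groups is None:
            self.contrast_groups = (
                (GroupLabel.DM,) if self.test_id is TestId.TEST3 else (GroupLabel.MDR,)
            )

    def validate(self) -> None:
        if self.c is not None and self.coverage is not None:
            raise ValidationError("TestConfig: give c or coverage, not both")
        if self.n_train < 10:
            raise ValidationError(f"n_train: {self.n_train} < 10")
        if self.test_id is TestId.TEST2 and any(
            s not in (20, 30, 40) for s in self.train_sizes
        ):
            raise ValidationError(
                f"train_sizes: {self.train_sizes} must be drawn from (20, 30, 40)"
            )
        for f in self.input_features + (self.target_feature,):
            if f not in ("TH", "TR", "FD"):
                raise ValidationError(f"unknown feature {f!r}")
        if self.n_repeats < 1:
            raise ValidationError(f"n_repeats: {self.n_repeats} < 1")

    @property
    def band_c(self) -> float:
        if self.coverage is not None:
            return discordance.c_from_coverage(self.coverage)
        return self.c if self.c is not None else discordance.DEFAULT_C


_FEATURE_COLUMN = {"TH": "TH_um", "TR": "TR", "FD": "FD"}


@dataclasses.dataclass
class MetricsRow:
    """Per-layer results of one experiment."""

    layer: LayerName
    counts: ConfusionCounts
    metrics: dict
    band: discordance.ErrorBand
    n_train: int
    repeat: int = 0

    def to_dict(self) -> dict:
        return {
            "layer": self.layer.value,
            "n_train": self.n_train,
            "repeat": self.repeat,
            "counts_eyes": self.counts.to_dict(),
            "counts_scans": self.counts.scans(),
            **{
                k: self.metrics[k]
                for k in ("sensitivity", "specificity", "ppv", "percent_correct")
            },
            "undefined": self.metrics["undefined"],
            "band": self.band.to_dict(),
        }


def eye_level_features(
    table: pd.DataFrame, layer: LayerName, region: RegionName
) -> pd.DataFrame:
    """Average the per-scan features of each eye for one layer and region.

    Returns one row per eye with columns eye_id, group, TH_um, TR, FD.
    """
    sel = table[
        (table["layer"] == layer.value) & (table["region"] == region.value)
    ]
    if sel.empty:
        raise OctbandError(f"no rows for layer {layer} in region {region}")
    agg = (
        sel.groupby(["eye_id", "group"], as_index=False)[["TH_um", "TR", "FD"]]
        .mean()
        .sort_values("eye_id", kind="stable")
        .reset_index(drop=True)
    )
    return agg


def _classify_layer(
    eyes: pd.DataFrame,
    train_ids: np.ndarray,
    cfg: TestConfig,
    seed: int,
) -> tuple[ConfusionCounts, discordance.ErrorBand]:
    """Fit reference model on training eyes, classify all remaining eyes."""
    cols = [_FEATURE_COLUMN[f] for f in cfg.input_features]
    tcol = _FEATURE_COLUMN[cfg.target_feature]

    is_train = eyes["eye_id"].isin(train_ids)
    train = eyes[is_train]
    test = eyes[~is_train]

    config = dataclasses.replace(cfg.brbf_config, rng_seed=seed)
    posterior = brbf.fit(train[cols].to_numpy(), train[tcol].to_numpy(), config)

    eps_train = discordance.relative_error(
        brbf.predict_mean(posterior, train[cols].to_numpy()),
        train[tcol].to_numpy(),
    )
    band = discordance.fit_error_band(eps_train, cfg.band_c)

    eps_test = discordance.relative_error(
        brbf.predict_mean(posterior, test[cols].to_numpy()),
        test[tcol].to_numpy(),
    )
    inside = discordance.classify(eps_test, band)

    positive_condition = test["group"] == cfg.reference_group.value
    tp = int(np.sum(inside & positive_condition))
    fn = int(np.sum(~inside & positive_condition))
    fp = int(np.sum(inside & ~positive_condition))
    tn = int(np.sum(~inside & ~positive_condition))
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp), band


def _draw_training_ids(
    eyes_ref: Sequence[str], n_train: int, rng: np.random.Generator
) -> np.ndarray:
    ids = np.asarray(sorted(eyes_ref))
    if n_train >= ids.size:
        raise ValidationError(
            f"n_train: {n_train} >= reference group size {ids.size}"
        )
    return rng.choice(ids, size=n_train, replace=False)


def run_reference_band_experiment(
    table: pd.DataFrame, cfg: TestConfig
) -> list[MetricsRow]:
    """Run one experiment (Test 1 or Test 3 layout) over all configured layers.

    For each layer: draw ``n_train`` reference-group eyes without replacement,
    fit the regressor input -> target on them, build the relative-error band
    with the configured c, classify every non-training eye, and tally the
    eye-level confusion counts.  With ``n_repeats > 1``, per-repeat rows are
    followed by a mean row (repeat = -1) holding averaged counts and the
    metrics recomputed from them.
    """
    cfg.validate()
    missing = [
        l.value
        for l in cfg.layers
        if table[
            (table["layer"] == l.value) & (table["region"] == cfg.region.value)
        ].empty
    ]
    if missing:
        raise OctbandError(f"missing layer data for region {cfg.region}: {missing}")

    all_groups = (cfg.reference_group,) + tuple(cfg.contrast_groups)
    rows: list[MetricsRow] = []
    for layer in cfg.layers:
        eyes = eye_level_features(table, layer, cfg.region)
        eyes = eyes[eyes["group"].isin([g.value for g in all_groups])]
        ref_ids = eyes.loc[
            eyes["group"] == cfg.reference_group.value, "eye_id"
        ].to_numpy()
        for rep in range(cfg.n_repeats):
            rng = np.random.default_rng((cfg.rng_seed, rep))
            train_ids = _draw_training_ids(ref_ids, cfg.n_train, rng)
            fit_seed = int(
                np.random.default_rng((cfg.rng_seed, rep, 1)).integers(2**31)
            )
            counts, band = _classify_layer(eyes, train_ids, cfg, fit_seed)
            rows.append(
                MetricsRow(
                    layer=layer,
                    counts=counts,
                    metrics=confusion_metrics(counts),
                    band=band,
                    n_train=cfg.n_train,
                    repeat=rep,
                )
            )
        if cfg.n_repeats > 1:
            reps = [r for r in rows if r.layer is layer and r.repeat >= 0]
            mean_counts = ConfusionCounts(
                tp=int(round(np.mean([r.counts.tp for r in reps]))),
                fn=int(round(np.mean([r.counts.fn for r in reps]))),
                tn=int(round(np.mean([r.counts.tn for r in reps]))),
                fp=int(round(np.mean([r.counts.fp for r in reps]))),
            )
            rows.append(
                MetricsRow(
                    layer=layer,
                    counts=mean_counts,
                    metrics=confusion_metrics(mean_counts),
                    band=reps[-1].band,
                    n_train=cfg.n_train,
                    repeat=-1,
                )
            )
    return rows


def run_test2(
    table: pd.DataFrame, base_cfg: TestConfig
) -> dict[int, list[MetricsRow]]:
    """Training-set-size sweep with nested training sets (20 within 30 within 40).

    Returns ``{n_train: rows}`` plus stability deltas of TN and FN across
    sizes under key ``-1`` is not used; deltas are available via
    :func:`test2_stability`.
    """
    base_cfg.validate()
    sizes = tuple(sorted(base_cfg.train_sizes))
    rng = np.random.default_rng((base_cfg.rng_seed, 2))
    # one nested draw per layer, reused across sizes
    results: dict[int, list[MetricsRow]] = {s: [] for s in sizes}
    for layer in base_cfg.layers:
        eyes = eye_level_features(table, layer, base_cfg.region)
        groups = (base_cfg.reference_group,) + tuple(base_cfg.contrast_groups)
        eyes = eyes[eyes["group"].isin([g.value for g in groups])]
        ref_ids = eyes.loc[
            eyes["group"] == base_cfg.reference_group.value, "eye_id"
        ].to_numpy()
        superset = _draw_training_ids(ref_ids, max(sizes), rng)
        for s in sizes:
            cfg = dataclasses.replace(
                base_cfg, test_id=TestId.TEST2, n_train=s, layers=(layer,)
            )
            fit_seed = int(
                np.random.default_rng((base_cfg.rng_seed, 3, s)).integers(2**31)
            )
            counts, band = _classify_layer(eyes, superset[:s], cfg, fit_seed)
            results[s].append(
                MetricsRow(
                    layer=layer,
                    counts=counts,
                    metrics=confusion_metrics(counts),
                    band=band,
                    n_train=s,
                )
            )
    return results


def test2_stability(results: Mapping[int, list[MetricsRow]]) -> dict:
    """Max absolute change of TN and FN across training sizes, per layer."""
    sizes = sorted(results)
    layers = [r.layer for r in results[sizes[0]]]
    out = {}
    for i, layer in enumerate(layers):
        tns = [results[s][i].counts.tn for s in sizes]
        fns = [results[s][i].counts.fn for s in sizes]
        out[layer.value] = {
            "tn_delta": max(tns) - min(tns),
            "fn_delta": max(fns) - min(fns),
        }
    return out


def report(rows: Sequence[MetricsRow], cfg: TestConfig) -> tuple[str, str]:
    """Machine-readable JSON and an aligned markdown table (layers as columns)."""
    if not rows:
        raise ValidationError("report: no metrics rows")
    payload = {
        "config": {
            "test_id": cfg.test_id.value,
            "reference_group": cfg.reference_group.value,
            "contrast_groups": [g.value for g in cfg.contrast_groups],
            "n_train": cfg.n_train,
            "input_features": list(cfg.input_features),
            "target_feature": cfg.target_feature,
            "region": cfg.region.value,
            "c": cfg.band_c,
            "coverage": discordance.gaussian_error_function(cfg.band_c),
            "rng_seed": cfg.rng_seed,
            "n_repeats": cfg.n_repeats,
        },
        "rows": [r.to_dict() for r in rows],
    }
    js = json.dumps(payload, indent=2, sort_keys=True)

    layers = [r.layer.value for r in rows]
    header = "| metric | " + " | ".join(layers) + " |"
    sep = "|---" * (len(rows) + 1) + "|"

    def fmt(v):
        return f"{v:.2f}" if isinstance(v, float) else str(v)

    lines = [header, sep]
    for name, get in [
        ("TP (eye/scans)", lambda r: f"{r.counts.tp}/{r.counts.tp * SCANS_PER_EYE}"),
        ("FN (eye/scans)", lambda r: f"{r.counts.fn}/{r.counts.fn * SCANS_PER_EYE}"),
        ("TN (eye/scans)", lambda r: f"{r.counts.tn}/{r.counts.tn * SCANS_PER_EYE}"),
        ("FP (eye/scans)", lambda r: f"{r.counts.fp}/{r.counts.fp * SCANS_PER_EYE}"),
        ("PPV", lambda r: fmt(r.metrics["ppv"])),
        ("Sensitivity", lambda r: fmt(r.metrics["sensitivity"])),
        ("Specificity", lambda r: fmt(r.metrics["specificity"])),
    ]:
        lines.append("| " + name + " | " + " | ".join(get(r) for r in rows) + " |")
    return js, "\n".join(lines)
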