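"""Model-quality metrics and the repeated random sub-sampling protocol.

Three metrics are reported, all computed on denormalized (original-unit)
predictions:

* ``R``: the determination-style coefficient ``1 - SSE/SST`` (1 for a
  perfect fit, 0 for predicting the observed mean, negative when worse than
  the mean). The Pearson correlation is reported alongside as ``pearson_r``
  since "correlation coefficient" is often read either way.
* ``RMSE``: root-mean-square error in the PK parameter's own units.
* ``NRMSE``: RMSE divided by the observed range of the parameter, so models
  for differently-scaled parameters are comparable.

Validation follows repeated random sub-sampling: the compounds are split
uniformly at random into a training and a test group (33/6 for 39
compounds, proportionally otherwise), a fresh network is trained per split,
and metrics are aggregated across repeats. Split balance is checked with a
Levene variance-homogeneity test and a two-sample t-test on the PK values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ann import ANNConfig, forward, init_network, train_levenberg_marquardt
from .io_normalize import QSPkRDataset, ScaleInfo, denormalize

__all__ = [
    "SplitSpec",
    "EvaluationReport",
    "correlation_R",
    "pearson_r",
    "rmse",
    "nrmse",
    "split_train_test",
    "homogeneity_tests",
    "repeated_subsampling_validation",
]


@dataclass
class SplitSpec:
    """One random train/test partition of the compound indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.train_indices = np.asarray(self.train_indices, dtype=int)
        self.test_indices = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(self.train_indices, self.test_indices).size:
            raise ValueError("train and test indices overlap")


def correlation_R(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """``1 - sum((obs - pred)^2) / sum((obs - mean(obs))^2)``.

    No square root is taken; the value may be negative. A constant
    observed vector has zero denominator and raises.
    """
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("observed values are constant; R undefined")
    sse = float(np.sum((y_obs - y_pred) ** 2))
    return 1.0 - sse / sst


def pearson_r(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Ordinary Pearson correlation between observed and predicted values."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if np.std(y_pred) == 0.0 or np.std(y_obs) == 0.0:
        return float("nan")
    return float(np.corrcoef(y_obs, y_pred)[0, 1])


def rmse(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Root-mean-square prediction error, in the units of the inputs."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size == 0 or y_obs.shape != y_pred.shape:
        raise ValueError("need two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_obs - y_pred) ** 2)))


def nrmse(rmse_value: float, scale: ScaleInfo | tuple[float, float]) -> float:
    """RMSE divided by the observed range ``max - min`` of the parameter."""
    if isinstance(scale, ScaleInfo):
        lo, hi = float(scale.minimum[0]), float(scale.maximum[0])
    else:
        lo, hi = map(float, scale)
    if hi == lo:
        raise ValueError("observed range is zero; NRMSE undefined")
    return float(rmse_value) / (hi - lo)


def split_train_test(n_compounds: int, n_train: int,
                     seed: int | np.random.Generator | None = None) -> SplitSpec:
    """Uniform random partition into ``n_train`` training compounds and the rest."""
    if not 0 < n_train < n_compounds:
        raise ValueError("need 0 < n_train < n_compounds")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    perm = rng.permutation(n_compounds)
    return SplitSpec(
        train_indices=np.sort(perm[:n_train]),
        test_indices=np.sort(perm[n_train:]),
        seed=seed if isinstance(seed, int) else None,
    )


def homogeneity_tests(train_values: np.ndarray, test_values: np.ndarray,
                      center: str = "mean",
                      equal_var: bool = False) -> tuple[float, float]:
    """(Levene variance-homogeneity p, two-sample t-test p) for the split.

    Defaults: classical Levene (deviations from the mean) and Welch's
    t-test, appropriate for the unequal group sizes of a 33/6 split; set
    ``equal_var=True`` for the pooled-variance Student t-test.
    """
    a = np.asarray(train_values, dtype=float).ravel()
    b = np.asarray(test_values, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    levene_p = float(stats.levene(a, b, center=center).pvalue)
    t_p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return levene_p, t_p


@dataclass
class EvaluationReport:
    """Per-repeat and aggregate metrics from sub-sampling validation."""

    pk_name: str
    pk_unit: str | None
    n_train: int
    n_test: int
    n_repeats: int
    seed: int | None
    selected_indices: list[int]
    repeats: list[dict] = field(default_factory=list)
    aggregate: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pk_name": self.pk_name,
            "pk_unit": self.pk_unit,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_repeats": self.n_repeats,
            "seed": self.seed,
            "selected_indices": list(map(int, self.selected_indices)),
            "repeats": self.repeats,
            "aggregate": self.aggregate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _metric_block(y_obs_orig, y_pred_orig, y_obs_norm, y_pred_norm,
                  scale: ScaleInfo) -> dict:
    e = rmse(y_obs_orig, y_pred_orig)
    return {
        "R": correlation_R(y_obs_orig, y_pred_orig),
        "pearson_r": pearson_r(y_obs_orig, y_pred_orig),
        "RMSE": e,
        "NRMSE": nrmse(e, scale),
        "RMSE_normalized": rmse(y_obs_norm, y_pred_norm),
        "N": int(np.asarray(y_obs_orig).size),
    }


def repeated_subsampling_validation(
    data: QSPkRDataset,
    selected: list[int] | np.ndarray,
    ann_config: ANNConfig | None = None,
    n_repeats: int = 10,
    n_train: int | None = None,
    seed: int | None = None,
) -> EvaluationReport:
    """Train/test the network over ``n_repeats`` random splits.

    ``n_train`` defaults to the 33-of-39 proportion rounded to the nearest
    integer. Each repeat gets its own deterministic split and weight-init
    seed derived from ``seed``, so the whole protocol is reproducible.
    """
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("no descriptors selected")
    if selected.min() < 0 or selected.max() >= data.n_descriptors:
        raise ValueError("selected descriptor index out of range")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    n = data.n_compounds
    if n_train is None:
        n_train = int(round(n * 33 / 39))
        n_train = min(max(n_train, 1), n - 1)
    ann_config = ann_config or ANNConfig()

    Xsel = data.X[:, selected]
    y_norm = data.dp
    y_orig = denormalize(y_norm, data.pk_scale)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_repeats)
    report = EvaluationReport(
        pk_name=data.pk_name,
        pk_unit=data.pk_unit,
        n_train=n_train,
        n_test=n - n_train,
        n_repeats=n_repeats,
        seed=seed,
        selected_indices=[int(i) for i in selected],
    )
    for r, child in enumerate(children):
        split_rng, init_seed = np.random.default_rng(child), child.spawn(1)[0]
        split = split_train_test(n, n_train, split_rng)
        cfg = ANNConfig(**{**ann_config.__dict__,
                           "seed": int(init_seed.generate_state(1)[0] % (2 ** 31))})
        model = init_network(selected.size, cfg)
        model = train_levenberg_marquardt(
            model, Xsel[split.train_indices], y_norm[split.train_indices], cfg)

        rec: dict = {"repeat": r,
                     "train_indices": split.train_indices.tolist(),
                     "test_indices": split.test_indices.tolist()}
        for part, idx in (("train", split.train_indices),
                          ("test", split.test_indices)):
            pred_norm = forward(model, Xsel[idx])
            pred_orig = denormalize(pred_norm, data.pk_scale)
            rec[part] = _metric_block(y_orig[idx], pred_orig,
                                      y_norm[idx], pred_norm, data.pk_scale)
            rec[part]["pairs"] = [
                {"compound": data.compound_ids[i],
                 "observed": float(y_orig[i]), "predicted": float(p)}
                for i, p in zip(idx, pred_orig)
            ]
        lev_p, t_p = homogeneity_tests(y_orig[split.train_indices],
                                       y_orig[split.test_indices])
        rec["homogeneity"] = {"levene_p": lev_p, "ttest_p": t_p}
        report.repeats.append(rec)

    agg: dict = {}
    for part in ("train", "test"):
        for m in ("R", "pearson_r", "RMSE", "NRMSE", "RMSE_normalized"):
            vals = np.array([rec[part][m] for rec in report.repeats])
            agg[f"{part}_{m}_mean"] = float(np.nanmean(vals))
            agg[f"{part}_{m}_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0
        # pooled over all repeats: more stable than per-repeat metrics when
        # a test fold holds only a handful of compounds
        obs = np.array([p["observed"] for rec in report.repeats
                        for p in rec[part]["pairs"]])
        pred = np.array([p["predicted"] for rec in report.repeats
                         for p in rec[part]["pairs"]])
        e = rmse(obs, pred)
        agg[f"{part}_R_pooled"] = correlation_R(obs, pred)
        agg[f"{part}_pearson_r_pooled"] = pearson_r(obs, pred)
        agg[f"{part}_RMSE_pooled"] = e
        agg[f"{part}_NRMSE_pooled"] = nrmse(e, data.pk_scale)
    report.aggregate = agg
    return report
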