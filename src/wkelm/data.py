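"""Voice-measurement tables: the UCI Parkinson's CSV dialect and a synthetic
generator emulating its 22-feature schema.

The canonical table has one recording per row: a non-numeric identifier
column, 22 positive-valued dysphonia features on heterogeneous scales
(fundamental frequencies in Hz, jitter as small fractions, shimmer in dB and
ratio scales, noise-to-harmonics ratios, nonlinear dynamical measures) and a
binary ``status`` column separating Parkinson's disease (PD) recordings from
healthy controls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FEATURE_NAMES",
    "Dataset",
    "SimConfig",
    "DataFormatError",
    "read_uci_parkinsons",
    "write_csv",
    "simulate_dataset",
    "standardize_fit",
    "standardize_apply",
]

#: canonical feature columns of the UCI Parkinson's voice table, in file order
FEATURE_NAMES = (
    "MDVP:Fo(Hz)",
    "MDVP:Fhi(Hz)",
    "MDVP:Flo(Hz)",
    "MDVP:Jitter(%)",
    "MDVP:Jitter(Abs)",
    "MDVP:RAP",
    "MDVP:PPQ",
    "Jitter:DDP",
    "MDVP:Shimmer",
    "MDVP:Shimmer(dB)",
    "Shimmer:APQ3",
    "Shimmer:APQ5",
    "MDVP:APQ",
    "Shimmer:DDA",
    "NHR",
    "HNR",
    "RPDE",
    "DFA",
    "spread1",
    "spread2",
    "D2",
    "PPE",
)

_JITTER = FEATURE_NAMES[3:8]
_SHIMMER = FEATURE_NAMES[8:14]
#: features shifted between classes by the generator: jitter + shimmer + PPE
DEFAULT_SHIFT_FEATURES = _JITTER + _SHIMMER + ("PPE",)


class DataFormatError(ValueError):
    """Raised when an input table violates the expected CSV dialect."""


@dataclass
class Dataset:
    """A two-class feature table.

    ``positive_class`` is the label value meaning PD; sensitivity is computed
    with respect to it.
    """

    features: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    ids: np.ndarray | None = None
    positive_class: object = 1

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("labels length must match number of rows")
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length must match number of columns")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


def read_uci_parkinsons(path, positive_label_value=1) -> Dataset:
    """Read a UCI-Parkinson's-dialect CSV.

    Expects a header row, a binary ``status`` column, at most one non-numeric
    identifier column and numeric feature columns.  Missing or non-numeric
    feature cells are a hard error naming the offending row and column.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if "status" not in frame.columns:
        raise DataFormatError(f"{path}: no 'status' column in header")

    status = frame["status"]
    if status.isna().any():
        row = int(status.isna().idxmax())
        raise DataFormatError(f"{path}: missing 'status' value at row {row}")
    status_values = set(status.unique().tolist())
    if len(status_values) > 2 or not status_values <= {0, 1}:
        raise DataFormatError(
            f"{path}: 'status' must be binary 0/1, found values {sorted(status_values)}"
        )

    id_col = None
    feature_cols: list[str] = []
    for col in frame.columns:
        if col == "status":
            continue
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if frame[col].dtype == object and numeric.isna().all():
            if id_col is not None:
                raise DataFormatError(
                    f"{path}: multiple non-numeric columns ({id_col!r}, {col!r}); "
                    "expected a single identifier column"
                )
            id_col = col
            continue
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise DataFormatError(
                f"{path}: non-numeric value {frame[col][row]!r} in column "
                f"{col!r} at row {row}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax())
            raise DataFormatError(f"{path}: missing value in column {col!r} at row {row}")
        feature_cols.append(col)

    return Dataset(
        features=frame[feature_cols].to_numpy(dtype=float),
        feature_names=feature_cols,
        labels=frame["status"].to_numpy(),
        ids=None if id_col is None else frame[id_col].to_numpy(),
        positive_class=positive_label_value,
    )


def write_csv(dataset: Dataset, path) -> None:
    """Write a :class:`Dataset` back to the CSV dialect (round-trips exactly)."""
    frame = pd.DataFrame(dataset.features, columns=dataset.feature_names)
    if dataset.ids is not None:
        frame.insert(0, "name", dataset.ids)
    frame["status"] = dataset.labels
    # %.17g round-trips IEEE doubles exactly
    frame.to_csv(path, index=False, float_format="%.17g")


@dataclass
class SimConfig:
    """Configuration of the synthetic voice-table generator.

    effect_size is the standardized (latent, per-feature) mean shift between
    the PD and healthy classes on ``shift_features``; correlation is the
    shared within-block correlation inside the jitter and shimmer families.
    """

    n_samples: int = 192
    prevalence: float = 0.75
    effect_size: float = 1.5
    correlation: float = 0.7
    seed: int = 0
    shift_features: tuple[str, ...] = DEFAULT_SHIFT_FEATURES

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        n_pd = round(self.n_samples * self.prevalence)
        if min(n_pd, self.n_samples - n_pd) < 2:
            raise ValueError("each class must contain at least 2 samples")
        unknown = set(self.shift_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown shift features: {sorted(unknown)}")


# per-feature (log-)location and scale of the lognormal / affine transforms,
# roughly matching the magnitudes of the real table
_LOGNORMAL = {
    "MDVP:Jitter(%)": (np.log(0.006), 0.55),
    "MDVP:Jitter(Abs)": (np.log(4.5e-5), 0.55),
    "MDVP:RAP": (np.log(0.003), 0.6),
    "MDVP:PPQ": (np.log(0.0033), 0.6),
    "Jitter:DDP": (np.log(0.009), 0.6),
    "MDVP:Shimmer": (np.log(0.03), 0.5),
    "MDVP:Shimmer(dB)": (np.log(0.28), 0.5),
    "Shimmer:APQ3": (np.log(0.016), 0.5),
    "Shimmer:APQ5": (np.log(0.018), 0.5),
    "MDVP:APQ": (np.log(0.024), 0.5),
    "Shimmer:DDA": (np.log(0.047), 0.5),
    "PPE": (np.log(0.2), 0.4),
    "NHR": (np.log(0.025), 0.8),
}


def _block(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """k latent standard-normal columns with shared pairwise correlation rho."""
    shared = rng.standard_normal((n, 1))
    indep = rng.standard_normal((n, k))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indep


def simulate_dataset(config: SimConfig) -> Dataset:
    """Simulate a two-class voice-measurement table.

    Emulates the 22-feature schema: lognormal fundamental-frequency trio with
    ``Flo <= Fo <= Fhi`` enforced row-wise, positive jitter/shimmer families
    with within-family correlation, anticorrelated NHR/HNR, and nonlinear
    measures on their natural scales.  The PD class is shifted by
    ``effect_size`` latent standard deviations on ``shift_features``.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    n_pd = round(n * config.prevalence)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pd]] = 1
    is_pd = labels == 1

    latent: dict[str, np.ndarray] = {}
    jit = _block(rng, n, len(_JITTER), config.correlation)
    for j, name in enumerate(_JITTER):
        latent[name] = jit[:, j]
    shim = _block(rng, n, len(_SHIMMER), config.correlation)
    for j, name in enumerate(_SHIMMER):
        latent[name] = shim[:, j]
    for name in ("PPE", "NHR", "RPDE", "DFA", "spread1", "spread2", "D2"):
        latent[name] = rng.standard_normal(n)

    for name in config.shift_features:
        latent[name] = latent[name] + config.effect_size * is_pd

    cols: dict[str, np.ndarray] = {}
    # fundamental-frequency trio: lognormal Fo, multiplicative spread up/down
    z_f0 = rng.standard_normal(n)
    fo = np.exp(np.log(150.0) + 0.25 * z_f0)
    up = np.abs(0.20 + 0.15 * rng.standard_normal(n))
    down = np.clip(np.abs(0.20 + 0.12 * rng.standard_normal(n)), 0.0, 0.8)
    cols["MDVP:Fo(Hz)"] = fo
    cols["MDVP:Fhi(Hz)"] = fo * (1.0 + up)
    cols["MDVP:Flo(Hz)"] = fo * (1.0 - down)

    for name, (mu, sigma) in _LOGNORMAL.items():
        cols[name] = np.exp(mu + sigma * latent[name])
    # HNR decreases as NHR increases (shared latent, opposite sign)
    cols["HNR"] = 22.0 - 3.5 * latent["NHR"] + 1.0 * rng.standard_normal(n)
    cols["RPDE"] = np.clip(0.5 + 0.1 * latent["RPDE"], 0.01, 0.99)
    cols["DFA"] = np.clip(0.72 + 0.05 * latent["DFA"], 0.01, 0.99)
    cols["spread1"] = -5.7 + 0.9 * latent["spread1"]
    cols["spread2"] = np.abs(0.22 + 0.08 * latent["spread2"]) + 1e-3
    cols["D2"] = np.abs(2.4 + 0.35 * latent["D2"]) + 1e-3

    features = np.column_stack([cols[name] for name in FEATURE_NAMES])
    ids = np.array([f"sim_R{i + 1:04d}" for i in range(n)])
    return Dataset(
        features=features,
        feature_names=list(FEATURE_NAMES),
        labels=labels,
        ids=ids,
        positive_class=1,
    )


def standardize_fit(X) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (mean, sd) from training rows; constant features get sd 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("standardize_fit needs a 2-D matrix with >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def standardize_apply(stats: tuple[np.ndarray, np.ndarray], X) -> np.ndarray:
    """Apply z-scoring statistics from :func:`standardize_fit`."""
    mean, sd = stats
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty matrix")
    if X.shape[-1] != mean.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[-1]} does not match statistics ({mean.shape[0]})"
        )
    return (X - mean) / sd
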