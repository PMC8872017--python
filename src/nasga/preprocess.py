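"""Imputation, normalization and denoising of episode matrices.

Order of application: Gaussian-process imputation on the raw hourly values,
then per-feature z-scoring fitted on the training split only, then a
denoising autoencoder trained on the normalized training episodes and
applied uniformly to all splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import nn


class PreprocessError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gaussian-process imputation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GprConfig:
    """Squared-exponential kernel with fixed hyperparameters."""

    length_scale: float = 3.0
    signal_variance: float = 1.0
    noise_variance: float = 1e-4
    clamp_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.length_scale <= 0 or self.signal_variance <= 0 or self.noise_variance < 0:
            raise PreprocessError("GPR hyperparameters must be positive")


def _kernel(t1: np.ndarray, t2: np.ndarray, config: GprConfig) -> np.ndarray:
    d = t1[:, None] - t2[None, :]
    return config.signal_variance * np.exp(-0.5 * (d / config.length_scale) ** 2)


def gp_posterior_mean(
    t_obs: np.ndarray, y_obs: np.ndarray, t_query: np.ndarray, config: GprConfig
) -> np.ndarray:
    """Posterior mean at ``t_query`` given observations, with the observed
    mean as the prior mean."""
    t_obs = np.asarray(t_obs, dtype=np.float64)
    y_obs = np.asarray(y_obs, dtype=np.float64)
    t_query = np.asarray(t_query, dtype=np.float64)
    prior = float(y_obs.mean())
    k_ss = _kernel(t_obs, t_obs, config) + (config.noise_variance + 1e-10) * np.eye(len(t_obs))
    k_qs = _kernel(t_query, t_obs, config)
    alpha = cho_solve(cho_factor(k_ss, lower=True), y_obs - prior)
    return prior + k_qs @ alpha


def gpr_impute(series: np.ndarray, config: GprConfig | None = None) -> np.ndarray:
    """Fill the NaN entries of an hourly series with the GP posterior mean.

    Observed values are preserved.  Requires at least one observation.
    """
    config = config or GprConfig()
    series = np.asarray(series, dtype=np.float64)
    observed = ~np.isnan(series)
    if not observed.any():
        raise PreprocessError("gpr_impute requires at least one observed value")
    if observed.all():
        return series.copy()
    hours = np.arange(len(series), dtype=np.float64)
    out = series.copy()
    filled = gp_posterior_mean(hours[observed], series[observed], hours[~observed], config)
    if config.clamp_range is not None:
        filled = np.clip(filled, *config.clamp_range)
    out[~observed] = filled
    return out


def impute_episodes(
    x: np.ndarray,
    feature_means: np.ndarray,
    config: GprConfig | None = None,
) -> np.ndarray:
    """Impute a stack of episodes (n, hours, features).

    Features with zero observations in an episode fall back to the
    training-split feature mean.  Episodes share only ``2**hours`` possible
    missingness patterns per feature, so the GP solve is cached per pattern.
    """
    config = config or GprConfig()
    x = np.array(x, dtype=np.float64)
    n, hours, n_features = x.shape
    t = np.arange(hours, dtype=np.float64)
    weight_cache: dict[tuple[bool, ...], np.ndarray] = {}
    for f in range(n_features):
        col = x[:, :, f]  # n x hours
        masks = ~np.isnan(col)
        for pattern in np.unique(masks, axis=0):
            rows = np.flatnonzero((masks == pattern).all(axis=1))
            if pattern.all():
                continue
            if not pattern.any():
                col[rows] = feature_means[f]
                continue
            key = tuple(pattern)
            if key not in weight_cache:
                k_ss = _kernel(t[pattern], t[pattern], config)
                k_ss += (config.noise_variance + 1e-10) * np.eye(int(pattern.sum()))
                k_qs = _kernel(t[~pattern], t[pattern], config)
                weight_cache[key] = cho_solve(cho_factor(k_ss, lower=True), k_qs.T).T
            w = weight_cache[key]
            y = col[np.ix_(rows, np.flatnonzero(pattern))]
            prior = y.mean(axis=1, keepdims=True)
            filled = prior + (y - prior) @ w.T
            if config.clamp_range is not None:
                filled = np.clip(filled, *config.clamp_range)
            col[np.ix_(rows, np.flatnonzero(~pattern))] = filled
        x[:, :, f] = col
    return x


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class Normalizer:
    """Per-feature location/scale learned from the training split."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, train_x: np.ndarray) -> "Normalizer":
        flat = train_x.reshape(-1, train_x.shape[-1])
        mean = np.nanmean(flat, axis=0)
        scale = np.nanstd(flat, axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)  # constant-feature fallback
        return cls(mean=mean, scale=scale)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.scale

    def invert(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale + self.mean

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"version": 1, "mean": self.mean.tolist(), "scale": self.scale.tolist()})
        )

    @classmethod
    def load(cls, path: str | Path) -> "Normalizer":
        doc = json.loads(Path(path).read_text())
        return cls(mean=np.asarray(doc["mean"]), scale=np.asarray(doc["scale"]))


def fit_normalizer(train_x: np.ndarray) -> Normalizer:
    return Normalizer.fit(train_x)


def apply_normalizer(x: np.ndarray, normalizer: Normalizer) -> np.ndarray:
    return normalizer.apply(x)


# ---------------------------------------------------------------------------
# denoising autoencoder
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DaeConfig:
    #: encoder widths (wide layer, bottleneck); None -> (D, D // 2) for
    #: flattened episode width D; the decoder mirrors the encoder
    widths: tuple[int, int] | None = None
    corruption_std: float = 0.1
    epochs: int = 30
    learning_rate: float = 0.01
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.widths is not None and any(w < 1 for w in self.widths):
            raise PreprocessError("degenerate DAE configuration")
        if self.epochs < 1 or self.batch_size < 1:
            raise PreprocessError("degenerate DAE configuration")
        if self.corruption_std < 0:
            raise PreprocessError("corruption_std must be >= 0")


@dataclass
class Denoiser:
    """Symmetric two-layer encoder/decoder (tanh hidden layers, linear output)."""

    input_dim: int
    widths: tuple[int, int]
    episode_shape: tuple[int, int]
    params: dict[str, nn.Tensor] = field(default_factory=dict)

    def parameters(self) -> list[nn.Tensor]:
        return [self.params[k] for k in sorted(self.params)]

    def forward_flat(self, x: np.ndarray) -> nn.Tensor:
        p = self.params
        h = nn.tanh(nn.add(nn.matmul(nn.Tensor(x), p["W_enc1"]), p["b_enc1"]))
        z = nn.tanh(nn.add(nn.matmul(h, p["W_enc2"]), p["b_enc2"]))
        h2 = nn.tanh(nn.add(nn.matmul(z, p["W_dec1"]), p["b_dec1"]))
        return nn.add(nn.matmul(h2, p["W_dec2"]), p["b_dec2"])

    def transform(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1:] != self.episode_shape:
            raise PreprocessError(
                f"episode shape {x.shape[1:]} does not match trained denoiser {self.episode_shape}"
            )
        flat = x.reshape(len(x), -1)
        out = self.forward_flat(flat).data
        return out.reshape(x.shape)

    def save(self, archive: str | Path) -> None:
        arrays = {k: t.data for k, t in self.params.items()}
        np.savez(
            Path(archive),
            __meta__=np.array(
                [self.input_dim, *self.widths, *self.episode_shape], dtype=np.int64
            ),
            **arrays,
        )

    @classmethod
    def load(cls, archive: str | Path) -> "Denoiser":
        with np.load(Path(archive)) as data:
            meta = data["__meta__"]
            params = {
                k: nn.Tensor(np.array(data[k]), requires_grad=True)
                for k in data.files
                if k != "__meta__"
            }
        return cls(
            input_dim=int(meta[0]),
            widths=(int(meta[1]), int(meta[2])),
            episode_shape=(int(meta[3]), int(meta[4])),
            params=params,
        )


def train_dae(train_x: np.ndarray, config: DaeConfig | None = None) -> Denoiser:
    """Train the denoiser to reconstruct clean inputs from corrupted ones."""
    config = config or DaeConfig()
    n, hours, n_features = train_x.shape
    input_dim = hours * n_features
    widths = config.widths or (input_dim, max(1, input_dim // 2))
    wide, bottleneck = widths
    rng = np.random.default_rng(config.seed)

    def mat(rows: int, cols: int) -> nn.Tensor:
        std = np.sqrt(2.0 / (rows + cols))
        return nn.Tensor(rng.normal(0.0, std, size=(rows, cols)), requires_grad=True)

    model = Denoiser(
        input_dim=input_dim,
        widths=widths,
        episode_shape=(hours, n_features),
        params={
            "W_enc1": mat(input_dim, wide),
            "b_enc1": nn.Tensor(np.zeros(wide), requires_grad=True),
            "W_enc2": mat(wide, bottleneck),
            "b_enc2": nn.Tensor(np.zeros(bottleneck), requires_grad=True),
            "W_dec1": mat(bottleneck, wide),
            "b_dec1": nn.Tensor(np.zeros(wide), requires_grad=True),
            "W_dec2": mat(wide, input_dim),
            "b_dec2": nn.Tensor(np.zeros(input_dim), requires_grad=True),
        },
    )
    flat = train_x.reshape(n, -1)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            clean = flat[idx]
            corrupted = clean + config.corruption_std * rng.normal(size=clean.shape)
            opt.zero_grad()
            loss = nn.mse_loss(model.forward_flat(corrupted), clean)
            loss.backward()
            opt.step()
    return model


def denoise(x: np.ndarray, denoiser: Denoiser) -> np.ndarray:
    """Apply the trained denoiser; output shape equals input shape."""
    return denoiser.transform(x)
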