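"""Recurrent forecasters: minimal gated RNN and linear state-space cells.

The minimal RNN cell embeds the input, then mixes it with the previous
hidden state through a single forget gate:

    u_t = tanh(W_u x_t + b_u)
    f_t = sigmoid(U_h h_{t-1} + U_u u_t + b_f)
    h_t = f_t * h_{t-1} + (1 - f_t) * u_t

The linear state-space (LSS) cell is its gate-free linearization,
h_t = A h_{t-1} + B x_t + b.  Both share the same output heads: a softmax
over three diagnosis logits and an affine map for the 22 continuous
markers, each predicting the *next* timepoint.

Training minimizes a masked multi-task loss — cross-entropy on observed
diagnoses plus mean absolute error on observed continuous entries — with
Adam.  Missing entries never enter the loss.  Under the integrative "model
filling" strategy, missing *inputs* at step t are replaced by the model's
own prediction from step t-1 within the same forward pass, and gradients
flow through the filled values (a stop-gradient switch is available).

Everything here is plain numpy with hand-derived reverse-mode gradients;
the backward pass is validated against finite differences in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, NormStats, SubjectTrajectory
from .filling import fill_matrix
from .schema import DEFAULT_SCHEMA, FeatureSchema

__all__ = [
    "TrainConfig",
    "RecurrentForecaster",
    "init_params",
    "minimal_rnn_step",
    "lss_step",
    "predict_next",
    "sequence_loss",
    "train",
    "model_fill_forward",
    "forecast",
    "forecast_table_to_csv",
]

N_DX = 3


@dataclass
class TrainConfig:
    """Training hyperparameters (search ranges follow the tuning-space table).

    ``cell`` selects the architecture; dropout rates are active only during
    training (input dropout resampled per timepoint, recurrent dropout held
    fixed per sequence in variational style).  ``model_fill_gradients``
    controls whether gradients flow through model-filled inputs.
    """

    cell: str = "minimal_rnn"  # or "lss"
    hidden: int = 128
    layers: int = 1
    learning_rate: float = 3e-3
    l2: float = 1e-6
    input_dropout: float = 0.1
    recurrent_dropout: float = 0.1
    epochs: int = 50
    batch_size: int = 64
    lr_decay: float = 1.0  # multiplicative per-epoch decay of the step size
    seed: int = 0
    model_fill_gradients: bool = True
    val_every: int = 5  # epochs between validation-loss checks
    # LSS only: cap on the transition matrix's largest singular value, so
    # month-by-month recursive forecasts over long horizons cannot diverge
    max_transition_norm: float = 1.0
    # continuous predictions fed back as inputs (model filling, recursive
    # forecasting) are clipped to +/- this many z-units; real markers live
    # well inside that range, and the bound keeps the closed loop stable
    feedback_clip: float = 8.0


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def init_params(
    cfg: TrainConfig,
    rng: np.random.Generator,
    n_values: int = 25,
) -> dict[str, np.ndarray]:
    """Initialize a flat parameter dictionary for the configured cell."""
    n_cont = n_values - N_DX
    p: dict[str, np.ndarray] = {}
    for l in range(cfg.layers):
        d_in = n_values if l == 0 else cfg.hidden
        d = cfg.hidden
        if cfg.cell == "minimal_rnn":
            p[f"l{l}.Wx"] = _glorot(rng, (d, d_in))
            p[f"l{l}.bu"] = np.zeros(d)
            p[f"l{l}.Uh"] = _glorot(rng, (d, d))
            p[f"l{l}.Uu"] = _glorot(rng, (d, d))
            p[f"l{l}.bf"] = np.zeros(d)
        elif cfg.cell == "lss":
            # damped near-identity start with a small input matrix keeps
            # hidden-state norms moderate (the linear cell has no squashing
            # nonlinearity) and long recursive rollouts stable
            p[f"l{l}.A"] = 0.5 * np.eye(d) + 0.1 * _glorot(rng, (d, d))
            p[f"l{l}.B"] = 0.3 * _glorot(rng, (d, d_in))
            p[f"l{l}.b"] = np.zeros(d)
        else:
            raise ValueError(f"unknown cell {cfg.cell!r}")
    p["Ws"] = _glorot(rng, (N_DX, cfg.hidden))
    p["bs"] = np.zeros(N_DX)
    p["Wg"] = _glorot(rng, (n_cont, cfg.hidden))
    p["bg"] = np.zeros(n_cont)
    return p


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# --- single-step reference operations (vector in, vector out) --------------

def minimal_rnn_step(
    h_prev: np.ndarray, x_t: np.ndarray, params: dict[str, np.ndarray], layer: int = 0
) -> np.ndarray:
    """One minimal-RNN update for a single hidden/input vector pair."""
    l = f"l{layer}"
    u = np.tanh(params[f"{l}.Wx"] @ x_t + params[f"{l}.bu"])
    f = _sigmoid(params[f"{l}.Uh"] @ h_prev + params[f"{l}.Uu"] @ u + params[f"{l}.bf"])
    return f * h_prev + (1.0 - f) * u


def lss_step(
    h_prev: np.ndarray, x_t: np.ndarray, params: dict[str, np.ndarray], layer: int = 0
) -> np.ndarray:
    """One linear state-space update: h = A h_prev + B x + b."""
    l = f"l{layer}"
    return params[f"{l}.A"] @ h_prev + params[f"{l}.B"] @ x_t + params[f"{l}.b"]


def predict_next(
    h_t: np.ndarray, params: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Output heads: (softmax diagnosis probabilities, continuous predictions)."""
    probs = _softmax(h_t @ params["Ws"].T + params["bs"])
    g = h_t @ params["Wg"].T + params["bg"]
    return probs, g


# ---------------------------------------------------------------------------
# masked multi-task loss
# ---------------------------------------------------------------------------

def sequence_loss(
    probs: np.ndarray,
    g_hat: np.ndarray,
    targets: np.ndarray,
    observed: np.ndarray,
    n_cont_norm: int | None = None,
) -> float:
    """Masked loss of one sequence: sum over t >= 1 of CE + MAE.

    ``probs[t]``/``g_hat[t]`` predict timepoint t+1, so they align with
    ``targets[1:]``.  Cross-entropy is summed over timepoints with an
    observed diagnosis; absolute errors are summed over observed continuous
    entries and divided by the constant number of continuous variables, so
    the two terms are weighted equally and missing data never contributes.
    """
    targets = np.asarray(targets, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    T = targets.shape[0]
    if probs.shape[0] != T - 1 or g_hat.shape[0] != T - 1:
        raise ValueError("predictions must cover timepoints 1..T-1")
    n_cont = targets.shape[1] - N_DX
    if n_cont_norm is None:
        n_cont_norm = n_cont
    dx_obs = observed[1:, 0]
    cont_obs = observed[1:, 1:]
    if not dx_obs.any() and not cont_obs.any():
        raise ValueError("no observed target anywhere in the sequence")
    s_t = np.nan_to_num(targets[1:, :N_DX])
    ce = -np.sum(s_t[dx_obs] * np.log(np.clip(probs[dx_obs], 1e-12, None)))
    g_t = np.nan_to_num(targets[1:, N_DX:])
    mae = np.sum(np.abs(g_t - g_hat) * cont_obs) / n_cont_norm
    return float(ce + mae)


# ---------------------------------------------------------------------------
# batched forward / backward
# ---------------------------------------------------------------------------

def _expand_mask(obs: np.ndarray) -> np.ndarray:
    """(…, 23) feature mask -> (…, 25) value mask (diagnosis trio tied)."""
    return np.concatenate(
        [np.repeat(obs[..., :1], N_DX, axis=-1), obs[..., 1:]], axis=-1
    )


def _forward(
    params: dict[str, np.ndarray],
    cfg: TrainConfig,
    X_in: np.ndarray,  # (B, T, 25); NaN at unobserved when model filling
    obs: np.ndarray,  # (B, T, 23)
    valid: np.ndarray,  # (B, T)
    means: np.ndarray,  # (25,) fallback fill values
    strategy: str,
    training: bool,
    rng: np.random.Generator | None,
):
    """Unroll the cell over t = 0..T-2; returns predictions and a cache."""
    B, T, n_values = X_in.shape
    d, L = cfg.hidden, cfg.layers
    vmask = _expand_mask(obs)

    in_drop = cfg.input_dropout if training else 0.0
    rec_drop = cfg.recurrent_dropout if training else 0.0
    rmask = [
        (rng.random((B, d)) >= rec_drop) / (1.0 - rec_drop)
        if rec_drop > 0 else np.ones((B, d))
        for _ in range(L)
    ]

    h = [np.zeros((B, d)) for _ in range(L)]
    cache = {
        "x": [], "xmask": [], "v": [[] for _ in range(L)],
        "u": [[] for _ in range(L)], "f": [[] for _ in range(L)],
        "hp": [[] for _ in range(L)], "h": [[] for _ in range(L)],
        "rmask": rmask, "vmask": vmask,
    }
    probs_seq, ghat_seq = [], []
    cache["clip_active"] = []
    pred_prev: np.ndarray | None = None

    for t in range(T - 1):
        raw = X_in[:, t]
        if strategy == "model":
            fallback = means[None, :] if t == 0 else pred_prev
            x = np.where(vmask[:, t], np.nan_to_num(raw), fallback)
        else:
            x = np.where(np.isfinite(raw), raw, means[None, :])
        if in_drop > 0:
            dmask = (rng.random((B, n_values)) >= in_drop) / (1.0 - in_drop)
        else:
            dmask = np.ones((B, n_values))
        cache["x"].append(x)
        cache["xmask"].append(dmask)
        v = x * dmask
        for l in range(L):
            lp = f"l{l}"
            hp = h[l]
            if cfg.cell == "minimal_rnn":
                u = np.tanh(v @ params[f"{lp}.Wx"].T + params[f"{lp}.bu"])
                f = _sigmoid(
                    (hp * rmask[l]) @ params[f"{lp}.Uh"].T
                    + u @ params[f"{lp}.Uu"].T
                    + params[f"{lp}.bf"]
                )
                hn = f * hp + (1.0 - f) * u
                cache["u"][l].append(u)
                cache["f"][l].append(f)
            else:
                hn = (
                    (hp * rmask[l]) @ params[f"{lp}.A"].T
                    + v @ params[f"{lp}.B"].T
                    + params[f"{lp}.b"]
                )
            cache["v"][l].append(v)
            cache["hp"][l].append(hp)
            cache["h"][l].append(hn)
            h[l] = hn
            v = hn
        probs, g = predict_next(h[-1], params)
        probs_seq.append(probs)
        ghat_seq.append(g)
        c = cfg.feedback_clip
        cache["clip_active"].append(np.abs(g) < c)
        pred_prev = np.concatenate([probs, np.clip(g, -c, c)], axis=1)

    return np.array(probs_seq), np.array(ghat_seq), cache


def _loss_and_grads(
    params: dict[str, np.ndarray],
    cfg: TrainConfig,
    X_in: np.ndarray,
    X_tgt: np.ndarray,  # (B, T, 25) raw targets, NaN allowed
    obs: np.ndarray,
    valid: np.ndarray,
    means: np.ndarray,
    strategy: str,
    training: bool = True,
    rng: np.random.Generator | None = None,
):
    """Mean per-subject masked loss + L2 penalty, with gradients."""
    B, T, n_values = X_in.shape
    n_cont = n_values - N_DX
    probs_seq, ghat_seq, cache = _forward(
        params, cfg, X_in, obs, valid, means, strategy, training, rng
    )
    vmask = cache["vmask"]

    s_tgt = np.nan_to_num(X_tgt[..., :N_DX])
    g_tgt = np.nan_to_num(X_tgt[..., N_DX:])
    dx_m = (obs[:, :, 0] & valid).astype(float)
    g_m = (obs[:, :, 1:] & valid[:, :, None]).astype(float)

    loss = 0.0
    for t in range(T - 1):
        tau = t + 1
        p = np.clip(probs_seq[t], 1e-12, None)
        loss += -np.sum(s_tgt[:, tau] * np.log(p) * dx_m[:, tau, None])
        loss += np.sum(np.abs(g_tgt[:, tau] - ghat_seq[t]) * g_m[:, tau]) / n_cont
    loss /= B
    l2 = sum(
        np.sum(w ** 2) for k, w in params.items() if not k.endswith(("bu", "bf", "bs", "bg", ".b"))
    )
    loss += cfg.l2 * l2

    grads = {k: np.zeros_like(w) for k, w in params.items()}
    L, d = cfg.layers, cfg.hidden
    rmask = cache["rmask"]
    dh_carry = [np.zeros((B, d)) for _ in range(L)]
    dX_next: np.ndarray | None = None  # grad wrt inp[t+1] (pre-dropout)

    flow_fill = strategy == "model" and cfg.model_fill_gradients

    for t in range(T - 2, -1, -1):
        tau = t + 1
        probs, ghat = probs_seq[t], ghat_seq[t]
        dlogits = (probs - s_tgt[:, tau]) * dx_m[:, tau, None] / B
        dg = np.sign(ghat - g_tgt[:, tau]) * g_m[:, tau] / (n_cont * B)
        if flow_fill and dX_next is not None:
            fillm = ~vmask[:, tau]
            dp = dX_next[:, :N_DX] * fillm[:, :N_DX]
            dlogits += probs * (dp - np.sum(dp * probs, axis=1, keepdims=True))
            # the feedback clip is a hard saturation: no gradient when active
            dg += dX_next[:, N_DX:] * fillm[:, N_DX:] * cache["clip_active"][t]
        h_top = cache["h"][L - 1][t]
        grads["Ws"] += dlogits.T @ h_top
        grads["bs"] += dlogits.sum(axis=0)
        grads["Wg"] += dg.T @ h_top
        grads["bg"] += dg.sum(axis=0)
        dh = dlogits @ params["Ws"] + dg @ params["Wg"] + dh_carry[L - 1]

        for l in range(L - 1, -1, -1):
            lp = f"l{l}"
            v = cache["v"][l][t]
            hp = cache["hp"][l][t]
            if cfg.cell == "minimal_rnn":
                u, f = cache["u"][l][t], cache["f"][l][t]
                df = dh * (hp - u)
                da_f = df * f * (1.0 - f)
                grads[f"{lp}.Uh"] += da_f.T @ (hp * rmask[l])
                grads[f"{lp}.Uu"] += da_f.T @ u
                grads[f"{lp}.bf"] += da_f.sum(axis=0)
                du = dh * (1.0 - f) + da_f @ params[f"{lp}.Uu"]
                da_u = du * (1.0 - u ** 2)
                grads[f"{lp}.Wx"] += da_u.T @ v
                grads[f"{lp}.bu"] += da_u.sum(axis=0)
                dv = da_u @ params[f"{lp}.Wx"]
                dh_carry[l] = dh * f + (da_f @ params[f"{lp}.Uh"]) * rmask[l]
            else:
                grads[f"{lp}.A"] += dh.T @ (hp * rmask[l])
                grads[f"{lp}.B"] += dh.T @ v
                grads[f"{lp}.b"] += dh.sum(axis=0)
                dv = dh @ params[f"{lp}.B"]
                dh_carry[l] = (dh @ params[f"{lp}.A"]) * rmask[l]
            if l > 0:
                # layer below receives same-step input grad + its recurrence
                dh = dv + dh_carry[l - 1]
            else:
                dX_next = dv * cache["xmask"][t]
    for k, w in params.items():
        if not k.endswith(("bu", "bf", "bs", "bg", ".b")):
            grads[k] += 2.0 * cfg.l2 * w
    return loss, grads, probs_seq, ghat_seq


# ---------------------------------------------------------------------------
# data packing
# ---------------------------------------------------------------------------

def _pack(
    cohort: Cohort, means: np.ndarray, strategy: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Pad subjects to a common grid length; returns inputs, targets, masks."""
    subs = cohort.subjects
    B = len(subs)
    T = max(s.n_timepoints for s in subs)
    nv = cohort.schema.n_values
    nf = cohort.schema.n_features
    X_in = np.full((B, T, nv), np.nan)
    X_tgt = np.full((B, T, nv), np.nan)
    obs = np.zeros((B, T, nf), dtype=bool)
    valid = np.zeros((B, T), dtype=bool)
    for i, s in enumerate(subs):
        Ti = s.n_timepoints
        X_tgt[i, :Ti] = s.values
        X_in[i, :Ti] = fill_matrix(s, means, strategy)
        obs[i, :Ti] = s.observed
        valid[i, :Ti] = True
    return X_in, X_tgt, obs, valid, [s.subject_id for s in subs]


# ---------------------------------------------------------------------------
# Adam training loop
# ---------------------------------------------------------------------------

@dataclass
class FittedModel:
    """A trained forecaster: parameters + config + normalization statistics."""

    params: dict[str, np.ndarray]
    cfg: TrainConfig
    stats: NormStats
    fill_means: np.ndarray  # (25,) on the normalized scale
    strategy: str
    history: list[float] = field(default_factory=list)

    def save(self, path) -> None:
        meta = {
            "cfg": asdict(self.cfg),
            "strategy": self.strategy,
            "schema_version": 1,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            __mean__=self.stats.mean,
            __sd__=self.stats.sd,
            __fill_means__=self.fill_means,
            **self.params,
        )

    @classmethod
    def load(cls, path) -> "FittedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {
                k: z[k]
                for k in z.files
                if k not in ("__meta__", "__mean__", "__sd__", "__fill_means__")
            }
            stats = NormStats(mean=z["__mean__"], sd=z["__sd__"])
            fill_means = z["__fill_means__"]
        return cls(
            params=params,
            cfg=TrainConfig(**meta["cfg"]),
            stats=stats,
            fill_means=fill_means,
            strategy=meta["strategy"],
        )


# Backwards-friendly alias used around the package.
RecurrentForecaster = FittedModel


def train(
    train_cohort: Cohort,
    strategy: str,
    cfg: TrainConfig,
    stats: NormStats,
    fill_means: np.ndarray,
    val_cohort: Cohort | None = None,
    init_from: dict[str, np.ndarray] | None = None,
) -> FittedModel:
    """Fit a minimal-RNN or LSS forecaster with Adam on a normalized cohort.

    ``train_cohort`` must already be gridded and z-normalized; ``fill_means``
    are the training fallback values on the same scale.  With
    ``strategy="model"`` missing inputs are filled by the model itself during
    the forward pass.  When a validation cohort is given, the parameters with
    the lowest validation loss (checked every ``cfg.val_every`` epochs) are
    returned; otherwise the final parameters are.  Fully deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    nv = train_cohort.schema.n_values
    if init_from is not None:
        params = {k: w.copy() for k, w in init_from.items()}
    else:
        params = init_params(cfg, rng, n_values=nv)
    X_in, X_tgt, obs, valid, _ = _pack(train_cohort, fill_means, strategy)
    if val_cohort is not None and len(val_cohort):
        val_pack = _pack(val_cohort, fill_means, strategy)
    else:
        val_pack = None

    m = {k: np.zeros_like(w) for k, w in params.items()}
    v = {k: np.zeros_like(w) for k, w in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    best_val = np.inf
    best_params = None
    history: list[float] = []
    B = X_in.shape[0]

    for epoch in range(cfg.epochs):
        order = rng.permutation(B)
        epoch_loss = 0.0
        for start in range(0, B, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            loss, grads, _, _ = _loss_and_grads(
                params, cfg, X_in[idx], X_tgt[idx], obs[idx], valid[idx],
                fill_means, strategy, training=True, rng=rng,
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    "training diverged (loss is not finite); try a lower learning rate"
                )
            step += 1
            lr_epoch = cfg.learning_rate * cfg.lr_decay ** epoch
            lr_t = lr_epoch * np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
            for k in params:
                m[k] = b1 * m[k] + (1 - b1) * grads[k]
                v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
                params[k] = params[k] - lr_t * m[k] / (np.sqrt(v[k]) + eps)
            if cfg.cell == "lss" and cfg.max_transition_norm > 0:
                for k in params:
                    if k.endswith(".A"):
                        sv = np.linalg.norm(params[k], 2)
                        if sv > cfg.max_transition_norm:
                            params[k] *= cfg.max_transition_norm / sv
            epoch_loss += loss * len(idx)
        history.append(epoch_loss / B)
        if val_pack is not None and (epoch + 1) % cfg.val_every == 0:
            vl, _, _, _ = _loss_and_grads(
                params, cfg, val_pack[0], val_pack[1], val_pack[2], val_pack[3],
                fill_means, strategy, training=False, rng=None,
            )
            if vl < best_val:
                best_val = vl
                best_params = {k: w.copy() for k, w in params.items()}

    if best_params is not None:
        params = best_params
    return FittedModel(
        params=params, cfg=cfg, stats=stats, fill_means=fill_means,
        strategy=strategy, history=history,
    )


def training_loss(
    model: FittedModel, cohort: Cohort
) -> float:
    """Teacher-forced masked loss of a fitted model on a (normalized) cohort."""
    pack = _pack(cohort, model.fill_means, model.strategy)
    loss, _, _, _ = _loss_and_grads(
        model.params, model.cfg, pack[0], pack[1], pack[2], pack[3],
        model.fill_means, model.strategy, training=False, rng=None,
    )
    return float(loss)


# ---------------------------------------------------------------------------
# inference: model filling and recursive forecasting
# ---------------------------------------------------------------------------

def _run_inference(
    model: FittedModel, x_seq: np.ndarray
) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Consume a dense (T, 25) sequence; return per-step head outputs and h."""
    cfg, params = model.cfg, model.params
    L, d = cfg.layers, cfg.hidden
    h = [np.zeros(d) for _ in range(L)]
    probs_out, g_out = [], []
    for t in range(x_seq.shape[0]):
        v = x_seq[t]
        for l in range(L):
            step = minimal_rnn_step if cfg.cell == "minimal_rnn" else lss_step
            h[l] = step(h[l], v, params, layer=l)
            v = h[l]
        p, g = predict_next(h[-1], params)
        probs_out.append(p)
        g_out.append(g)
    return np.array(probs_out), np.array(g_out), h


def model_fill_forward(
    model: FittedModel, traj: SubjectTrajectory
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Integrative filling: scan the grid, replacing missing inputs with the
    model's one-step predictions; first-timepoint gaps take training means.

    Returns the dense (T, 25) filled sequence and the final hidden state(s).
    """
    cfg, params = model.cfg, model.params
    vmask = _expand_mask(traj.observed)
    T = traj.n_timepoints
    L, d = cfg.layers, cfg.hidden
    h = [np.zeros(d) for _ in range(L)]
    filled = np.zeros_like(traj.values)
    pred_prev = model.fill_means
    step = minimal_rnn_step if cfg.cell == "minimal_rnn" else lss_step
    for t in range(T):
        x = np.where(vmask[t], np.nan_to_num(traj.values[t]), pred_prev)
        filled[t] = x
        v = x
        for l in range(L):
            h[l] = step(h[l], v, params, layer=l)
            v = h[l]
        p, g = predict_next(h[-1], params)
        c = model.cfg.feedback_clip
        pred_prev = np.concatenate([p, np.clip(g, -c, c)])
    return filled, h


def forecast(
    model: FittedModel,
    input_traj: SubjectTrajectory,
    horizon_months: int,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> pd.DataFrame:
    """Recursive any-horizon forecast for one subject.

    Consumes the (normalized, gridded) input trajectory with the model's fill
    strategy, then feeds its own predictions back as inputs, one grid step at
    a time.  Grid-step predictions are linearly interpolated to a 1-month
    resolution and continuous markers are mapped back to their natural units.
    Returns a frame with one row per future month (relative months
    1..horizon after the last input month) carrying the diagnosis
    probability 3-vector, every continuous marker, and ventricles/ICV.
    """
    if horizon_months <= 0:
        raise ValueError("forecast horizon must be positive")
    res = input_traj.resolution
    if model.strategy == "model":
        filled, h = model_fill_forward(model, input_traj)
    else:
        filled = fill_matrix(input_traj, model.fill_means, model.strategy)
        _, _, h = _run_inference(model, filled)

    params, cfg = model.params, model.cfg
    step = minimal_rnn_step if cfg.cell == "minimal_rnn" else lss_step
    last_month = int(input_traj.grid_months[-1])
    n_steps = int(np.ceil(horizon_months / res))
    months, probs_list, g_list = [last_month], [], []
    # month-`last` anchor for interpolation: the (filled) last input
    anchor_probs = filled[-1, :N_DX]
    if anchor_probs.sum() <= 0:
        anchor_probs = np.full(N_DX, 1.0 / N_DX)
    probs_list.append(anchor_probs / anchor_probs.sum())
    g_list.append(filled[-1, N_DX:])

    clip = model.cfg.feedback_clip
    h = [hi.copy() for hi in h]
    for k in range(1, n_steps + 1):
        p, g = predict_next(h[-1], params)
        g = np.clip(g, -clip, clip)
        months.append(last_month + k * res)
        probs_list.append(p)
        g_list.append(g)
        x = np.concatenate([p, g])
        v = x
        for l in range(cfg.layers):
            h[l] = step(h[l], v, params, layer=l)
            v = h[l]

    grid_m = np.array(months, dtype=float)
    probs_arr = np.array(probs_list)
    g_arr = np.array(g_list)
    out_m = np.arange(last_month + 1, last_month + horizon_months + 1)
    probs_m = np.stack(
        [np.interp(out_m, grid_m, probs_arr[:, c]) for c in range(N_DX)], axis=1
    )
    probs_m = probs_m / probs_m.sum(axis=1, keepdims=True)
    g_m = np.stack(
        [np.interp(out_m, grid_m, g_arr[:, j]) for j in range(g_arr.shape[1])], axis=1
    )
    g_nat = g_m * model.stats.sd + model.stats.mean

    df = pd.DataFrame({
        "subject_id": input_traj.subject_id,
        "month": out_m,
        "p_NC": probs_m[:, 0],
        "p_MCI": probs_m[:, 1],
        "p_AD": probs_m[:, 2],
    })
    for j, name in enumerate(schema.continuous_names):
        df[name] = g_nat[:, j]
    vent = schema.continuous_index("Ventricles")
    icv = schema.continuous_index("ICV")
    df["ventricles_icv"] = g_nat[:, vent] / g_nat[:, icv]
    df["adas13"] = g_nat[:, schema.continuous_index("ADAS13")]
    return df


def forecast_table_to_csv(df: pd.DataFrame, path) -> None:
    """Write the TADPOLE-like forecast column subset."""
    cols = ["subject_id", "month", "p_NC", "p_MCI", "p_AD", "adas13", "ventricles_icv"]
    df[cols].to_csv(path, index=False)
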