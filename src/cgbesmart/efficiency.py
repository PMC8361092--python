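"""Window-ensemble neural model of per-position C-to-G editing efficiency.

For every protospacer position (1-20) the model holds an ensemble of nine
feed-forward base networks — window sizes 7, 9 and 11, three independently
initialized replicates each — over a shared learned nucleotide embedding
(A/C/G/T/PAD, 16 dimensions).  Each base network sees the embedded window
centered on the queried position (flanks and PAM included, PAD beyond the
available sequence), passes it through hidden layers of 256 and 128 rectified
linear units, and emits a single sigmoid output.  The ensemble prediction is
the weighted average of the nine outputs, with nonnegative combination
weights obtained by a softmax over nine learned logits so the "average" is
literal.  Training minimizes mean squared error over (site, substrate-C)
pairs with 30% dropout on the hidden layers, Adam updates, and
early stopping on validation Pearson R; the checkpoint with the best
validation R seen during training is returned.

Implemented directly in numpy (forward and backward passes are hand-written);
everything is float32 and fully reproducible from the configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import PositionEfficiency, TargetSite, ValidationError

SYMBOLS = ("A", "C", "G", "T", "PAD")
_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}
PAD = "PAD"
EMBED_DIM = 16
WINDOW_SIZES = (7, 9, 11)
REPLICATES_PER_WINDOW = 3
HIDDEN = (256, 128)
MAX_WINDOW = max(WINDOW_SIZES)


@dataclass
class TrainConfig:
    """Training schedule; architecture constants live at module level."""

    seed: int = 0
    epochs: int = 60
    batch_size: int = 256
    lr: float = 1e-3
    patience: int = 8
    dropout: float = 0.3

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def extract_window(site: TargetSite, position: int, w: int) -> list[str]:
    """Symbols of the window of odd width ``w`` centered on ``position``.

    Drawn from the full sequence (flanks and PAM included); positions beyond
    the available sequence are PAD.
    """
    if w % 2 == 0:
        raise ValidationError(f"window size must be odd, got {w}")
    if not 1 <= position <= 20:
        raise ValidationError(f"position {position} outside 1-20")
    half = w // 2
    out = []
    for p in range(position - half, position + half + 1):
        idx = site.seq_index(p)
        out.append(site.sequence[idx] if 0 <= idx < len(site.sequence) else PAD)
    return out


def window_indices(site: TargetSite, position: int, w: int = MAX_WINDOW) -> np.ndarray:
    return np.array(
        [_SYM_INDEX[s] for s in extract_window(site, position, w)], dtype=np.int64
    )


def _slice_for(w: int) -> slice:
    off = (MAX_WINDOW - w) // 2
    return slice(off, off + w)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


def _init_base_model(rng: np.random.Generator, w: int) -> dict:
    d_in = w * EMBED_DIM
    h1, h2 = HIDDEN
    return {
        "w": w,
        "W1": (rng.standard_normal((d_in, h1)) * np.sqrt(2.0 / d_in)).astype(np.float32),
        "b1": np.zeros(h1, dtype=np.float32),
        "W2": (rng.standard_normal((h1, h2)) * np.sqrt(2.0 / h1)).astype(np.float32),
        "b2": np.zeros(h2, dtype=np.float32),
        "W3": (rng.standard_normal((h2, 1)) * np.sqrt(1.0 / h2)).astype(np.float32),
        "b3": np.zeros(1, dtype=np.float32),
    }


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


class _Adam:
    """Minimal Adam with per-parameter step counters."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.state: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}

    def update(self, key: str, param: np.ndarray, grad: np.ndarray) -> None:
        m, v, t = self.state.get(
            key, (np.zeros_like(param), np.zeros_like(param), 0)
        )
        t += 1
        m = self.b1 * m + (1 - self.b1) * grad
        v = self.b2 * v + (1 - self.b2) * grad * grad
        self.state[key] = (m, v, t)
        mhat = m / (1 - self.b1**t)
        vhat = v / (1 - self.b2**t)
        param -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(param.dtype)


# ---------------------------------------------------------------------------
# The ensemble
# ---------------------------------------------------------------------------


class EfficiencyEnsemble:
    """Per-position window ensembles over a shared nucleotide embedding."""

    def __init__(self, config: TrainConfig, data_hash: str = ""):
        self.config = config
        self.data_hash = data_hash
        rng = np.random.default_rng(config.seed)
        self.embedding = (rng.standard_normal((len(SYMBOLS), EMBED_DIM)) * 0.1).astype(
            np.float32
        )
        self.positions: dict[int, dict] = {}
        for pos in range(1, 21):
            models = [
                _init_base_model(rng, w)
                for w in WINDOW_SIZES
                for _ in range(REPLICATES_PER_WINDOW)
            ]
            self.positions[pos] = {
                "models": models,
                "alpha": np.zeros(len(models), dtype=np.float32),
            }

    # -- forward ------------------------------------------------------------

    def _model_forward(
        self, model: dict, idx: np.ndarray, rng: np.random.Generator | None
    ):
        """Forward one base model; dropout active iff ``rng`` is given."""
        w = model["w"]
        emb = self.embedding[idx[:, _slice_for(w)]]  # (B, w, 16)
        x = emb.reshape(emb.shape[0], -1)
        a1 = x @ model["W1"] + model["b1"]
        h1 = np.maximum(a1, 0.0)
        cache = {"x": x, "a1": a1}
        rate = self.config.dropout
        if rng is not None and rate > 0:
            m1 = (rng.random(h1.shape) >= rate).astype(np.float32) / (1.0 - rate)
            h1 = h1 * m1
            cache["m1"] = m1
        a2 = h1 @ model["W2"] + model["b2"]
        h2 = np.maximum(a2, 0.0)
        cache.update(h1=h1, a2=a2)
        if rng is not None and rate > 0:
            m2 = (rng.random(h2.shape) >= rate).astype(np.float32) / (1.0 - rate)
            h2 = h2 * m2
            cache["m2"] = m2
        z = (h2 @ model["W3"]).ravel() + model["b3"][0]
        y = 1.0 / (1.0 + np.exp(-z))
        cache.update(h2=h2, y=y)
        return y, cache

    def ensemble_forward(
        self, pos: int, idx: np.ndarray, rng: np.random.Generator | None = None
    ):
        ens = self.positions[pos]
        lam = _softmax(ens["alpha"].astype(np.float64)).astype(np.float32)
        outs, caches = [], []
        for model in ens["models"]:
            y, cache = self._model_forward(model, idx, rng)
            outs.append(y)
            caches.append(cache)
        ys = np.stack(outs)  # (9, B)
        pred = lam @ ys
        return pred, ys, lam, caches

    def combination_weights(self, pos: int) -> np.ndarray:
        """Softmax-normalized combination weights (nonnegative, sum to 1)."""
        return _softmax(self.positions[pos]["alpha"].astype(np.float64))

    # -- backward -----------------------------------------------------------

    def _train_batch(
        self,
        pos: int,
        idx: np.ndarray,
        target: np.ndarray,
        rng: np.random.Generator,
        opt: _Adam,
    ) -> float:
        ens = self.positions[pos]
        pred, ys, lam, caches = self.ensemble_forward(pos, idx, rng)
        B = idx.shape[0]
        g = (2.0 / B) * (pred - target)  # dL/dpred, L = MSE

        # combination logits through the softmax
        s = ys @ g  # (9,)
        d_alpha = lam * (s - float(lam @ s))
        opt.update(f"p{pos}:alpha", ens["alpha"], d_alpha.astype(np.float32))

        d_emb = np.zeros_like(self.embedding)
        for j, (model, cache) in enumerate(zip(ens["models"], caches)):
            y = cache["y"]
            dz = (g * lam[j]) * y * (1.0 - y)  # (B,)
            h2, h1, x = cache["h2"], cache["h1"], cache["x"]
            dW3 = h2.T @ dz[:, None]
            db3 = np.array([dz.sum()], dtype=np.float32)
            dh2 = dz[:, None] @ model["W3"].T
            if "m2" in cache:
                dh2 = dh2 * cache["m2"]
            da2 = dh2 * (cache["a2"] > 0)
            dW2 = h1.T @ da2
            db2 = da2.sum(axis=0)
            dh1 = da2 @ model["W2"].T
            if "m1" in cache:
                dh1 = dh1 * cache["m1"]
            da1 = dh1 * (cache["a1"] > 0)
            dW1 = x.T @ da1
            db1 = da1.sum(axis=0)
            dx = da1 @ model["W1"].T
            w = model["w"]
            np.add.at(d_emb, idx[:, _slice_for(w)], dx.reshape(B, w, EMBED_DIM))
            key = f"p{pos}:m{j}"
            opt.update(f"{key}:W1", model["W1"], dW1)
            opt.update(f"{key}:b1", model["b1"], db1)
            opt.update(f"{key}:W2", model["W2"], dW2)
            opt.update(f"{key}:b2", model["b2"], db2)
            opt.update(f"{key}:W3", model["W3"], dW3)
            opt.update(f"{key}:b3", model["b3"], db3)
        opt.update("emb", self.embedding, d_emb)
        return float(np.mean((pred - target) ** 2))

    # -- prediction ---------------------------------------------------------

    def predict_windows(self, pos: int, idx: np.ndarray) -> np.ndarray:
        """Deterministic (dropout-off) predictions for pre-built windows."""
        pred, _, _, _ = self.ensemble_forward(pos, idx, rng=None)
        return pred

    def predict_site(self, site: TargetSite) -> dict[int, float]:
        """Efficiency per substrate-C position; non-C positions are absent."""
        out = {}
        for pos in site.substrate_positions():
            idx = window_indices(site, pos)[None, :]
            out[pos] = float(self.predict_windows(pos, idx)[0])
        return out

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {"embedding": self.embedding}
        for pos, ens in self.positions.items():
            arrays[f"p{pos}_alpha"] = ens["alpha"]
            for j, model in enumerate(ens["models"]):
                for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
                    arrays[f"p{pos}_m{j}_{name}"] = model[name]
        meta = {"config": asdict(self.config), "data_hash": self.data_hash,
                "window_sizes": list(WINDOW_SIZES)}
        arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EfficiencyEnsemble":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            obj = cls(TrainConfig(**meta["config"]), meta["data_hash"])
            obj.embedding = data["embedding"].copy()
            for pos, ens in obj.positions.items():
                ens["alpha"] = data[f"p{pos}_alpha"].copy()
                for j, model in enumerate(ens["models"]):
                    for name in ("W1", "b1", "W2", "b2", "W3", "b3"):
                        model[name] = data[f"p{pos}_m{j}_{name}"].copy()
        return obj

    def _snapshot(self) -> dict:
        return {
            "embedding": self.embedding.copy(),
            "positions": {
                pos: {
                    "alpha": ens["alpha"].copy(),
                    "models": [
                        {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in m.items()}
                        for m in ens["models"]
                    ],
                }
                for pos, ens in self.positions.items()
            },
        }

    def _restore(self, snap: dict) -> None:
        self.embedding = snap["embedding"].copy()
        for pos, ens in snap["positions"].items():
            self.positions[pos]["alpha"] = ens["alpha"].copy()
            for m_dst, m_src in zip(self.positions[pos]["models"], ens["models"]):
                for k, v in m_src.items():
                    m_dst[k] = v.copy() if isinstance(v, np.ndarray) else v


# ---------------------------------------------------------------------------
# Data preparation and training
# ---------------------------------------------------------------------------


def _prepare(
    sites: Mapping[str, TargetSite],
    labels: pd.DataFrame,
    site_ids: Iterable[str],
) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Per position: (window index matrix, label vector) for the given sites."""
    wanted = set(site_ids)
    per_pos: dict[int, tuple[list, list]] = {}
    for row in labels.itertuples(index=False):
        if row.site_id not in wanted:
            continue
        site = sites[row.site_id]
        pos = int(row.position)
        if site.base_at(pos) != "C":
            raise ValidationError(
                f"label at non-C position {pos} of site {row.site_id!r}"
            )
        if not 0.0 <= row.efficiency <= 1.0:
            raise ValidationError(f"label {row.efficiency} outside [0,1]")
        idxs, ys = per_pos.setdefault(pos, ([], []))
        idxs.append(window_indices(site, pos))
        ys.append(float(row.efficiency))
    return {
        pos: (np.stack(idxs), np.array(ys, dtype=np.float32))
        for pos, (idxs, ys) in per_pos.items()
    }


def _labels_hash(labels: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(labels.to_csv(index=False).encode())
    return h.hexdigest()[:16]


def train_efficiency_model(
    sites: Mapping[str, TargetSite],
    labels: pd.DataFrame,
    train_ids: Sequence[str],
    val_ids: Sequence[str],
    config: TrainConfig | None = None,
) -> tuple[EfficiencyEnsemble, list[float]]:
    """Train the ensemble; returns (best-validation checkpoint, history).

    ``labels`` must carry columns site_id, position, efficiency with labels
    only at reference-C positions.  Train and validation sites must be
    disjoint; the returned history lists the pooled validation Pearson R per
    epoch, and the returned model is the checkpoint with the best validation
    R seen during training.
    """
    config = config or TrainConfig()
    if set(train_ids) & set(val_ids):
        raise ValidationError("train and validation sites overlap")
    train_data = _prepare(sites, labels, train_ids)
    val_data = _prepare(sites, labels, val_ids)
    if not val_data:
        raise ValidationError("empty validation set")
    if not train_data:
        raise ValidationError("empty training set")

    model = EfficiencyEnsemble(config, data_hash=_labels_hash(labels))
    opt = _Adam(config.lr)
    rng = np.random.default_rng([config.seed, 1])

    val_idx = {p: d[0] for p, d in val_data.items()}
    val_y = np.concatenate([val_data[p][1] for p in sorted(val_data)])

    def validation_score() -> tuple[tuple[int, float], float]:
        """(sortable score, Pearson R).  When R is undefined (e.g. constant
        labels) model selection falls back to negative validation RMSE; any
        defined R outranks every undefined one."""
        preds = np.concatenate(
            [model.predict_windows(p, val_idx[p]) for p in sorted(val_data)]
        )
        rmse = float(np.sqrt(np.mean((preds - val_y) ** 2)))
        if preds.std() == 0 or val_y.std() == 0:
            return (0, -rmse), float("-inf")
        r = np.corrcoef(preds.astype(np.float64), val_y.astype(np.float64))[0, 1]
        if not np.isfinite(r):
            return (0, -rmse), float("-inf")
        return (1, float(r)), float(r)

    history: list[float] = []
    best_score = (-1, float("-inf"))
    best_snap = model._snapshot()
    wait = 0
    order = sorted(train_data)
    for _epoch in range(config.epochs):
        for pos in order:
            idx, y = train_data[pos]
            perm = rng.permutation(len(y))
            for start in range(0, len(y), config.batch_size):
                sl = perm[start : start + config.batch_size]
                model._train_batch(pos, idx[sl], y[sl], rng, opt)
        score, r = validation_score()
        history.append(r)
        if score > best_score:
            best_score = score
            best_snap = model._snapshot()
            wait = 0
        else:
            wait += 1
            if wait > config.patience:
                break
    model._restore(best_snap)
    return model, history


def predict_efficiency(
    model: EfficiencyEnsemble, site: TargetSite
) -> list[PositionEfficiency]:
    """Per-position predictions for one site (substrate Cs only)."""
    return [
        PositionEfficiency(site.site_id, pos, value)
        for pos, value in sorted(model.predict_site(site).items())
    ]


def predict_frame(
    model: EfficiencyEnsemble, sites: Iterable[TargetSite]
) -> pd.DataFrame:
    """Batched predictions for many sites (site_id, position, efficiency)."""
    per_pos: dict[int, tuple[list, list]] = {}
    for site in sites:
        for pos in site.substrate_positions():
            ids, idxs = per_pos.setdefault(pos, ([], []))
            ids.append(site.site_id)
            idxs.append(window_indices(site, pos))
    rows = []
    for pos in sorted(per_pos):
        ids, idxs = per_pos[pos]
        preds = model.predict_windows(pos, np.stack(idxs))
        rows.extend((sid, pos, float(v)) for sid, v in zip(ids, preds))
    return pd.DataFrame(rows, columns=["site_id", "position", "efficiency"]).sort_values(
        ["site_id", "position"], ignore_index=True
    )
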