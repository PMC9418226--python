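"""scikit-learn-style estimator wrapping the segmentation network.

``AttentionUNetSegmenter`` is the package's primary surface: it trains
either the plain or the attention-gated U-Net on stacks of grayscale
images with binary lesion masks and predicts soft-label probability
maps.  For progression prediction, simply pass the registered follow-up
masks as ``y`` -- the estimator is agnostic to which visit the labels
come from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .metrics import evaluate_pair
from .model import SegmentationModel, binarize
from .nn.network import NetworkConfig, UNet
from .nn.optim import Adam

__all__ = ["AttentionUNetSegmenter"]


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-7
    p = np.clip(prob, eps, 1 - eps)
    return float(np.mean(-y * np.log(p) - (1 - y) * np.log(1 - p)))


class AttentionUNetSegmenter(BaseEstimator):
    """Soft-labeled segmentation network with optional attention gates.

    Parameters
    ----------
    depth, base_filters, f_int_ratio, temperature, attended
        Architecture knobs; see :class:`~fafseg.nn.network.NetworkConfig`.
    loss
        ``"bce"`` (pixelwise binary cross-entropy on the soft output,
        the default) or ``"dice"`` (soft Dice).
    learning_rate, batch_size, epochs, patience
        Adam step size, minibatch size, epoch budget and early-stopping
        patience on validation loss (``patience=None`` disables early
        stopping; it is only active when validation data is supplied).
    random_state
        Seeds both weight initialization and minibatch shuffling.

    Attributes (after fit)
    ----------------------
    model_ : SegmentationModel      the trained network (best-validation
                                    checkpoint when validation data was given)
    history_ : pandas.DataFrame     per-epoch train/validation loss
    n_epochs_ : int                 epochs actually run
    """

    def __init__(
        self,
        depth: int = 3,
        base_filters: int = 8,
        f_int_ratio: float = 0.5,
        temperature: float = 1.0,
        attended: bool = True,
        loss: str = "bce",
        learning_rate: float = 1e-3,
        batch_size: int = 4,
        epochs: int = 30,
        patience: int | None = 10,
        shuffle: bool = True,
        random_state: int = 0,
        verbose: int = 0,
    ):
        self.depth = depth
        self.base_filters = base_filters
        self.f_int_ratio = f_int_ratio
        self.temperature = temperature
        self.attended = attended
        self.loss = loss
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.shuffle = shuffle
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, H, W), got shape {X.shape}")
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} must match X shape {X.shape}")
        if not np.isin(np.unique(y), (0, 1)).all():
            raise ValueError("y must be binary {0,1} masks")
        if X.shape[1] != X.shape[2]:
            raise ValueError("images must be square")
        return X, y.astype(np.float32)

    def _loss_and_grad(self, prob, yb):
        n_pix = prob.size
        if self.loss == "bce":
            loss = _bce(prob, yb)
            dlogits = (prob - yb) / n_pix
        elif self.loss == "dice":
            inter = float((prob * yb).sum())
            denom = float(prob.sum() + yb.sum()) + 1.0
            loss = 1.0 - (2.0 * inter + 1.0) / denom
            dprob = -(2.0 * yb * denom - (2.0 * inter + 1.0)) / denom**2
            dlogits = dprob * prob * (1.0 - prob)
        else:
            raise ValueError(f"unknown loss {self.loss!r}")
        return loss, dlogits.astype(np.float32)

    def fit(self, X, y, validation_data=None):
        """Train on images ``X`` (n, H, W) with binary masks ``y``."""
        X, y = self._validate_xy(X, y)
        n, H, _ = X.shape
        config = NetworkConfig(
            depth=self.depth,
            base_filters=self.base_filters,
            f_int_ratio=self.f_int_ratio,
            temperature=self.temperature,
            input_size=H,
            attended=self.attended,
            seed=self.random_state,
        )
        net = UNet(config)
        opt = Adam(net.params, self.learning_rate)
        rng = np.random.default_rng(self.random_state)

        X_val = y_val = None
        if validation_data is not None:
            X_val, y_val = self._validate_xy(*validation_data)

        history = []
        best_val = np.inf
        best_params = None
        best_epoch = -1
        n_stale = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n) if self.shuffle else np.arange(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx][:, None]
                yb = y[idx][:, None]
                prob = net.forward(xb, train=True)
                loss, dlogits = self._loss_and_grad(prob, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}: {loss}; "
                        "reduce the learning rate or check the inputs"
                    )
                grads = net.backward(dlogits)
                opt.step(grads)
                losses.append(loss)
            train_loss = float(np.mean(losses))
            val_loss = np.nan
            if X_val is not None:
                val_loss = self._eval_loss(net, X_val, y_val)
                if val_loss < best_val - 1e-7:
                    best_val = val_loss
                    best_params = net.copy_params()
                    best_epoch = epoch
                    n_stale = 0
                else:
                    n_stale += 1
            history.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
            )
            if self.verbose:
                print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}")
            if (
                X_val is not None
                and self.patience is not None
                and n_stale > self.patience
            ):
                break

        if best_params is not None:
            net.set_params_(best_params)
        self.best_epoch_ = best_epoch if best_params is not None else len(history) - 1
        self.model_ = SegmentationModel(config, net)
        self.history_ = pd.DataFrame(history)
        self.n_epochs_ = len(history)
        return self

    def _eval_loss(self, net: UNet, X, y) -> float:
        losses = []
        for start in range(0, len(X), self.batch_size):
            xb = X[start:start + self.batch_size][:, None]
            yb = y[start:start + self.batch_size][:, None]
            prob = net.forward(xb)
            losses.append(self._loss_and_grad(prob, yb)[0] * len(xb))
        return float(np.sum(losses) / len(X))

    # ------------------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """Soft-label probability maps, shape (n, H, W)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[None]
        out = []
        for start in range(0, len(X), self.batch_size):
            prob = self.model_.net.forward(X[start:start + self.batch_size][:, None])
            out.append(prob[:, 0])
        return np.concatenate(out, axis=0)

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        """Binary masks from the thresholded probability maps."""
        return binarize(self.predict_proba(X), threshold)

    def score(self, X, y) -> float:
        """Mean per-image Dice coefficient."""
        preds = self.predict(X)
        y = np.asarray(y)
        return float(
            np.mean([evaluate_pair(p, t).dice for p, t in zip(preds, y)])
        )
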