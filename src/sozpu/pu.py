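"""Positive-unlabeled training via the unbiased risk estimator.

Setting: only a subset of SOZ (positive, y = +1) segments is labeled; the
rest of the data is an unlabeled mixture of SOZ and non-SOZ with known class
prior ``pi_p = p(y = +1)``. The supervised risk

    R_pn(g) = pi_p * R_p+(g) + pi_n * R_n-(g)

cannot be evaluated because no negative sample is identified, but since the
unlabeled marginal is the mixture ``p = pi_p p_p + pi_n p_n``, the
negative-class term rewrites as ``pi_n R_n- = R_u- - pi_p R_p-``, giving the
unbiased positive-unlabeled risk

    R_pu(g) = pi_p * R_p+(g) + R_u-(g) - pi_p * R_p-(g),

where R_p+/R_p- are the mean losses of the labeled positives scored toward
+1/-1 and R_u- the mean loss of the unlabeled set scored toward -1. With a
flexible model the estimated negative part can go below zero (a sign of
overfitting the labeled positives); the non-negative correction floors it:
``pi_p R_p+ + max(0, R_u- - pi_p R_p-)``, with a defitting gradient step on
the floored term.

The classifier ``g`` is a three-layer fully connected net with a single
output score, trained by minibatch Adam on this risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler

from . import _nn
from .classifiers import TrainResult
from .core_io import ConfigError, NONSOZ, SOZ


# ---------------------------------------------------------------------------
# losses and risks


def sigmoid_loss(z: np.ndarray, target: int) -> np.ndarray:
    """Bounded sigmoid loss l(z, t) = 1 / (1 + exp(t * z)), in [0, 1]."""
    return 1.0 / (1.0 + np.exp(np.clip(target * z, -500, 500)))


def sigmoid_loss_grad(z: np.ndarray, target: int) -> np.ndarray:
    s = sigmoid_loss(z, target)
    return -target * s * (1.0 - s)


def logistic_loss(z: np.ndarray, target: int) -> np.ndarray:
    """Convex logistic loss l(z, t) = ln(1 + exp(-t * z))."""
    tz = np.clip(target * z, -500, 500)
    return np.log1p(np.exp(-tz))


def logistic_loss_grad(z: np.ndarray, target: int) -> np.ndarray:
    return -target / (1.0 + np.exp(np.clip(target * z, -500, 500)))


def zero_one_loss(z: np.ndarray, target: int) -> np.ndarray:
    return (np.sign(z) != target).astype(float)


_LOSSES = {
    "sigmoid": (sigmoid_loss, sigmoid_loss_grad),
    "logistic": (logistic_loss, logistic_loss_grad),
    "zero_one": (zero_one_loss, None),
}


def _loss_fn(loss):
    if callable(loss):
        return loss
    try:
        return _LOSSES[loss][0]
    except KeyError:
        raise ConfigError(f"unknown loss {loss!r}") from None


def empirical_risk(g_scores: np.ndarray, target: int, loss="sigmoid") -> float:
    """Mean loss of scores ``g(x)`` measured toward class ``target`` (+1/-1)."""
    g_scores = np.asarray(g_scores, dtype=float)
    if g_scores.size == 0:
        raise ConfigError("empty score vector")
    if not np.all(np.isfinite(g_scores)):
        raise ConfigError("scores must be finite")
    if target not in (-1, 1):
        raise ConfigError("target must be +1 or -1")
    return float(np.mean(_loss_fn(loss)(g_scores, target)))


@dataclass
class PURiskComponents:
    """Decomposed empirical risks and their combination."""

    r_p_plus: float
    r_p_minus: float
    r_u_minus: float
    r_pu: float
    pi_p: float
    corrected: bool = False


def pu_risk(
    g_scores_p: np.ndarray,
    g_scores_u: np.ndarray,
    pi_p: float,
    loss="sigmoid",
    nn_correction: bool = False,
) -> PURiskComponents:
    """Unbiased positive-unlabeled risk of classifier scores.

    Without correction ``r_pu = pi_p * r_p_plus + r_u_minus - pi_p * r_p_minus``
    exactly; with ``nn_correction`` the (estimated) negative-class part is
    floored at zero.
    """
    if not 0 < pi_p < 1:
        raise ConfigError(f"pi_p must lie in (0, 1), got {pi_p}")
    r_p_plus = empirical_risk(g_scores_p, +1, loss)
    r_p_minus = empirical_risk(g_scores_p, -1, loss)
    r_u_minus = empirical_risk(g_scores_u, -1, loss)
    negative_part = r_u_minus - pi_p * r_p_minus
    if nn_correction:
        r_pu = pi_p * r_p_plus + max(0.0, negative_part)
    else:
        r_pu = pi_p * r_p_plus + negative_part
    return PURiskComponents(
        r_p_plus=r_p_plus,
        r_p_minus=r_p_minus,
        r_u_minus=r_u_minus,
        r_pu=float(r_pu),
        pi_p=pi_p,
        corrected=nn_correction and negative_part < 0,
    )


def supervised_risk(g_scores_p, g_scores_n, pi_p: float, loss="sigmoid") -> float:
    """Fully supervised risk pi_p * R_p+ + pi_n * R_n- (reference/oracle form)."""
    return pi_p * empirical_risk(g_scores_p, +1, loss) + (1 - pi_p) * empirical_risk(
        g_scores_n, -1, loss
    )


def prior_from_composition(n_pos_total: int, n_labeled: int, n_unlabeled: int) -> float:
    """Class prior of the unlabeled set when the composition is known.

    pi_p = (n_pos_total - n_labeled) / n_unlabeled — the fraction of the
    unlabeled rows that are positives once ``n_labeled`` positives have been
    revealed.
    """
    if min(n_pos_total, n_labeled, n_unlabeled) < 0 or n_unlabeled == 0:
        raise ConfigError("counts must be positive")
    if n_labeled > n_pos_total:
        raise ConfigError("cannot label more positives than exist")
    pi_p = (n_pos_total - n_labeled) / n_unlabeled
    if not 0 < pi_p < 1:
        raise ConfigError(f"implied prior {pi_p} outside (0, 1)")
    return pi_p


# ---------------------------------------------------------------------------
# training


@dataclass
class PUTrainConfig:
    loss: str = "sigmoid"
    nn_correction: bool = True
    epochs: int = 100
    batch: int = 64
    lr: float = 1e-3
    seed: int = 0


class PUClassifier(BaseEstimator, ClassifierMixin):
    """Three-layer fully connected net trained on the PU risk.

    ``fit(X, s)`` follows the PU convention: ``s == 1`` marks labeled
    positives (SOZ), ``s == 0`` unlabeled rows; the class prior of the
    unlabeled marginal must be supplied as ``pi_p``. Each minibatch draws
    from the labeled and unlabeled pools proportionally so all three risk
    terms are estimated at every step.
    """

    def __init__(self, pi_p: float = 0.5, hidden=(32, 32), loss: str = "sigmoid",
                 nn_correction: bool = True, epochs: int = 100, batch_size: int = 64,
                 lr: float = 1e-3, seed: int = 0):
        self.pi_p = pi_p
        self.hidden = hidden
        self.loss = loss
        self.nn_correction = nn_correction
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def fit(self, X, s, eval_set=None):
        if not 0 < self.pi_p < 1:
            raise ConfigError(f"pi_p must lie in (0, 1), got {self.pi_p}")
        if self.loss not in ("sigmoid", "logistic"):
            raise ConfigError("training loss must be 'sigmoid' or 'logistic'")
        X = np.asarray(X, dtype=float)
        s = np.asarray(s).astype(int)
        X_p, X_u = X[s == 1], X[s == 0]
        if len(X_p) == 0 or len(X_u) == 0:
            raise ConfigError("need both labeled-positive and unlabeled rows")
        self.scaler_ = StandardScaler().fit(X)
        Xp = self.scaler_.transform(X_p)
        Xu = self.scaler_.transform(X_u)
        lfn, lgrad = _LOSSES[self.loss]

        rng = np.random.default_rng(self.seed)
        net = _nn.make_mlp(X.shape[1], tuple(self.hidden), 1, rng)
        opt = _nn.Adam(net.params, lr=self.lr)
        n_u = len(Xu)
        bp = max(1, int(round(self.batch_size * len(Xp) / (len(Xp) + n_u))))
        bu = max(1, self.batch_size - bp)
        trace = []
        for _epoch in range(self.epochs):
            order_u = rng.permutation(n_u)
            for start in range(0, n_u, bu):
                iu = order_u[start:start + bu]
                ip = rng.integers(0, len(Xp), size=bp)
                xb = np.vstack([Xp[ip], Xu[iu]])
                z = net.forward(xb)[:, 0]
                zp, zu = z[:bp], z[bp:]
                r_p_minus = float(np.mean(lfn(zp, -1)))
                r_u_minus = float(np.mean(lfn(zu, -1)))
                negative_part = r_u_minus - self.pi_p * r_p_minus
                gp = self.pi_p * lgrad(zp, +1) / bp
                if self.nn_correction and negative_part < 0:
                    # defitting step: ascend the floored negative part
                    gp = gp - (-self.pi_p) * lgrad(zp, -1) / bp
                    gu = -lgrad(zu, -1) / len(iu)
                else:
                    gp = gp + (-self.pi_p) * lgrad(zp, -1) / bp
                    gu = lgrad(zu, -1) / len(iu)
                grad = np.concatenate([gp, gu])[:, None]
                net.backward(grad)
                opt.step()
            if eval_set is not None:
                Xe, ye = eval_set
                acc = 100.0 * float(np.mean(self._predict_net(net, Xe) == np.asarray(ye)))
                trace.append(acc)
        self.net_ = net
        self.epoch_trace_ = np.asarray(trace) if trace else np.empty(0)
        self.classes_ = np.array([NONSOZ, SOZ], dtype=object)
        return self

    def _predict_net(self, net, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        z = net.forward(Xs)[:, 0]
        return np.where(z > 0, SOZ, NONSOZ).astype(object)

    def decision_function(self, X):
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return self.net_.forward(Xs)[:, 0]

    def predict(self, X):
        if len(np.asarray(X)) == 0:
            return np.empty(0, dtype=object)
        return self._predict_net(self.net_, X)


def train_pu(
    X_p: np.ndarray,
    X_u: np.ndarray,
    pi_p: float,
    cfg: PUTrainConfig | None = None,
    hidden=(32, 32),
    eval_set=None,
) -> TrainResult:
    """Train the PU classifier from explicit positive/unlabeled pools."""
    cfg = cfg or PUTrainConfig()
    X_p = np.asarray(X_p, dtype=float)
    X_u = np.asarray(X_u, dtype=float)
    X = np.vstack([X_p, X_u])
    s = np.concatenate([np.ones(len(X_p), dtype=int), np.zeros(len(X_u), dtype=int)])
    clf = PUClassifier(
        pi_p=pi_p,
        hidden=hidden,
        loss=cfg.loss,
        nn_correction=cfg.nn_correction,
        epochs=cfg.epochs,
        batch_size=cfg.batch,
        lr=cfg.lr,
        seed=cfg.seed,
    ).fit(X, s, eval_set=eval_set)
    return TrainResult(model=clf, epoch_trace=clf.epoch_trace_, standardizer=clf.scaler_)
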