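"""Numba kernels for the MLP training loop.

The pipeline trains thousands of small networks (one per probe per
resample during screening; one per marker per resample during inference),
each with per-sample online weight updates, so the inner loops are
compiled.  Weight layout, shared with :mod:`anninfer.mlp`:

* ``W1``: ``(n_inputs + 1, H)`` — input-to-hidden weights; the last row is
  the hidden-layer bias (a fixed +1 input appended to the input vector).
* ``W2``: ``(H + 1,)`` — hidden-to-output weights; the last entry is the
  output bias.

All units are logistic-sigmoid.  The loss is squared error
``E = 1/2 (output - target)^2``; updates follow gradient descent with
momentum, ``dw = -lr * dE/dw + momentum * dw_prev``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@njit(cache=True)
def forward_one(W1, W2, x, hidden):
    """Forward pass for one sample; fills `hidden`, returns the output."""
    n_in = W1.shape[0] - 1
    H = W2.shape[0] - 1
    for j in range(H):
        z = W1[n_in, j]
        for i in range(n_in):
            z += W1[i, j] * x[i]
        hidden[j] = _sigmoid(z)
    z = W2[H]
    for j in range(H):
        z += W2[j] * hidden[j]
    return _sigmoid(z)


@njit(cache=True)
def gradient_one(W1, W2, x, y, gW1, gW2, hidden):
    """Analytic gradient of E = 1/2 (out - y)^2; fills gW1/gW2, returns out."""
    n_in = W1.shape[0] - 1
    H = W2.shape[0] - 1
    out = forward_one(W1, W2, x, hidden)
    d_out = (out - y) * out * (1.0 - out)
    for j in range(H):
        gW2[j] = d_out * hidden[j]
    gW2[H] = d_out
    for j in range(H):
        d_h = d_out * W2[j] * hidden[j] * (1.0 - hidden[j])
        for i in range(n_in):
            gW1[i, j] = d_h * x[i]
        gW1[n_in, j] = d_h
    return out


@njit(cache=True)
def step_one(W1, W2, vW1, vW2, x, y, lr, mom, gW1, gW2, hidden):
    """One online backprop update with momentum, in place."""
    gradient_one(W1, W2, x, y, gW1, gW2, hidden)
    n_in1 = W1.shape[0]
    H = W2.shape[0] - 1
    for j in range(H):
        for i in range(n_in1):
            vW1[i, j] = -lr * gW1[i, j] + mom * vW1[i, j]
            W1[i, j] += vW1[i, j]
    for j in range(H + 1):
        vW2[j] = -lr * gW2[j] + mom * vW2[j]
        W2[j] += vW2[j]


@njit(cache=True)
def mse_subset(W1, W2, X, y, idx, hidden):
    """Mean squared error of the network over the rows of X indexed by idx."""
    total = 0.0
    for k in range(idx.shape[0]):
        out = forward_one(W1, W2, X[idx[k]], hidden)
        total += (out - y[idx[k]]) ** 2
    return total / idx.shape[0]


@njit(cache=True)
def train_loop(W1, W2, X, y, shuffles, test_idx, lr, mom, patience):
    """Online training with per-epoch reshuffling and early stopping.

    Parameters
    ----------
    shuffles : (max_epochs, n_train) int64
        Pre-drawn visiting order of training-sample row indices per epoch.
    test_idx : int64 array
        Row indices monitored for early stopping.

    Returns
    -------
    bestW1, bestW2 : weight snapshot at the epoch of best test MSE
    train_mse, test_mse : per-epoch traces (length = epochs actually run)
    best_epoch : 0-based index of the selected epoch
    diverged : True if any weight became non-finite (training aborted)
    """
    max_epochs, n_train = shuffles.shape
    H = W2.shape[0] - 1
    hidden = np.empty(H)
    gW1 = np.empty_like(W1)
    gW2 = np.empty_like(W2)
    vW1 = np.zeros_like(W1)
    vW2 = np.zeros_like(W2)
    bestW1 = W1.copy()
    bestW2 = W2.copy()
    train_mse = np.empty(max_epochs)
    test_mse = np.empty(max_epochs)
    best = np.inf
    best_epoch = 0
    wait = 0
    n_run = 0
    diverged = False
    train_rows = shuffles[0].copy()  # any order; MSE is order-free
    for epoch in range(max_epochs):
        for k in range(n_train):
            step_one(W1, W2, vW1, vW2, X[shuffles[epoch, k]],
                     y[shuffles[epoch, k]], lr, mom, gW1, gW2, hidden)
        if not (np.all(np.isfinite(W1)) and np.all(np.isfinite(W2))):
            diverged = True
            break
        train_mse[epoch] = mse_subset(W1, W2, X, y, train_rows, hidden)
        test_mse[epoch] = mse_subset(W1, W2, X, y, test_idx, hidden)
        n_run = epoch + 1
        if test_mse[epoch] < best:
            best = test_mse[epoch]
            best_epoch = epoch
            bestW1[:] = W1
            bestW2[:] = W2
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                break
    return bestW1, bestW2, train_mse[:n_run], test_mse[:n_run], best_epoch, diverged


@njit(cache=True)
def predict_batch(W1, W2, X):
    """Network output for every row of X."""
    n = X.shape[0]
    H = W2.shape[0] - 1
    hidden = np.empty(H)
    out = np.empty(n)
    for i in range(n):
        out[i] = forward_one(W1, W2, X[i], hidden)
    return out
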