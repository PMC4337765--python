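"""Temporally correlated random sequences via Gaussian spectral low-pass filtering.

The whole simulator rests on one primitive: draw i.i.d. noise, transform to
the frequency domain, damp every frequency component by a Gaussian envelope
``exp(-omega^2 / (2 sigma^2))`` with ``sigma = n / cutoff_period``, and
transform back.  The result is a stationary sequence whose fluctuations occur
over periods of order ``cutoff_period`` steps or longer.  The filter gain at
zero frequency is exactly 1, so the sample mean is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrelatedSequence",
    "gaussian_lowpass_filter",
    "correlated_sequence",
    "normalize_by_max_abs",
    "rescale_to_std",
]

#: Base distributions understood by :func:`correlated_sequence`.
BASE_DISTRIBUTIONS = ("uniform_half", "standard_normal")


def gaussian_lowpass_filter(values: np.ndarray, cutoff_period: float) -> np.ndarray:
    """Low-pass filter a real sequence with a Gaussian spectral envelope.

    The discrete spectrum of ``values`` is multiplied by
    ``exp(-omega^2 / (2 sigma^2))`` where ``omega`` runs over the standard
    two-sided integer frequency grid ``{0, 1, ..., n/2, -(n/2 - 1), ..., -1}``
    of the length-``n`` transform and ``sigma = n / cutoff_period``.  The
    envelope is even in ``omega``, so conjugate symmetry — and hence realness —
    is preserved.  Boundary handling is circular (periodic), inherited from
    the discrete Fourier transform; no detrending or windowing is applied.

    Parameters
    ----------
    values : array_like of float, shape (n,)
        Input sequence, ``n >= 2``.
    cutoff_period : float
        Correlation cut-off period in time steps; fluctuations faster than
        this are suppressed.  Must be positive.  A cut-off of 1 sets
        ``sigma = n`` and the filter is close to all-pass.

    Returns
    -------
    numpy.ndarray of float, shape (n,)
        The filtered sequence.  Its mean equals the input mean to numerical
        tolerance (DC gain is ``exp(0) = 1``).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError(f"input must be a 1-d sequence of length >= 2, got shape {x.shape}")
    if not cutoff_period > 0:
        raise ValueError(f"cutoff_period must be positive, got {cutoff_period!r}")
    n = x.size
    # integer frequency indices 0, 1, ..., n/2, -(n/2-1), ..., -1
    omega = np.fft.fftfreq(n, d=1.0 / n)
    sigma = n / cutoff_period
    envelope = np.exp(-(omega**2) / (2.0 * sigma**2))
    return np.fft.ifft(np.fft.fft(x) * envelope).real


@dataclass(frozen=True)
class CorrelatedSequence:
    """A seeded, low-pass-filtered random sequence.

    Attributes
    ----------
    values : numpy.ndarray
        The filtered sequence, length ``n``.
    cutoff_period : float
        Correlation cut-off period in steps used for the filter.
    base_distribution : str
        Either ``"uniform_half"`` (i.i.d. uniform on [-0.5, 0.5]) or
        ``"standard_normal"`` (i.i.d. N(0, 1)).
    seed : object
        The seed (integer or :class:`numpy.random.SeedSequence`) the draw was
        made from, recorded for reproducibility; ``None`` when the sequence
        was drawn from a caller-supplied generator.
    """

    values: np.ndarray
    cutoff_period: float
    base_distribution: str
    seed: object = field(default=None, compare=False)

    def __len__(self) -> int:
        return self.values.size


def correlated_sequence(
    n: int,
    cutoff_period: float,
    base_distribution: str = "uniform_half",
    seed=None,
    rng: np.random.Generator | None = None,
) -> CorrelatedSequence:
    """Draw ``n`` i.i.d. values and low-pass filter them.

    Parameters
    ----------
    n : int
        Sequence length, at least 2.
    cutoff_period : float
        Correlation cut-off period in steps (see
        :func:`gaussian_lowpass_filter`).
    base_distribution : {"uniform_half", "standard_normal"}
        Marginal distribution of the raw draws before filtering.
    seed : int or numpy.random.SeedSequence, optional
        Seed for a fresh generator.  Ignored when ``rng`` is given.
    rng : numpy.random.Generator, optional
        Pre-built generator (e.g. a deterministic substream of a master
        seed); takes precedence over ``seed``.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if base_distribution not in BASE_DISTRIBUTIONS:
        raise ValueError(
            f"unknown base_distribution {base_distribution!r}; expected one of {BASE_DISTRIBUTIONS}"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    if base_distribution == "uniform_half":
        raw = rng.uniform(-0.5, 0.5, size=n)
    else:
        raw = rng.standard_normal(n)
    filtered = gaussian_lowpass_filter(raw, cutoff_period)
    return CorrelatedSequence(
        values=filtered,
        cutoff_period=float(cutoff_period),
        base_distribution=base_distribution,
        seed=seed,
    )


def normalize_by_max_abs(values: np.ndarray) -> np.ndarray:
    """Divide a sequence by its maximum absolute value.

    The output lies in [-1, 1] and attains magnitude 1 at least once; it is
    invariant under multiplication of the input by any positive scalar.  An
    all-zero input is rejected (the division is undefined).
    """
    x = np.asarray(values, dtype=float)
    peak = np.max(np.abs(x))
    if peak == 0:
        raise ValueError("cannot normalize an all-zero sequence by its maximum absolute value")
    return x / peak


def rescale_to_std(values: np.ndarray, target_std: float) -> np.ndarray:
    """Rescale a sequence so its sample standard deviation equals ``target_std``.

    The sample standard deviation uses the n-1 divisor.  Rescaling is a pure
    multiplication, so the correlation structure (and the autocorrelation
    function) of the input is preserved exactly.
    """
    if not target_std > 0:
        raise ValueError(f"target_std must be positive, got {target_std!r}")
    x = np.asarray(values, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot rescale a zero-variance sequence to a target standard deviation")
    return x * (target_std / sd)
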