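"""Synthetic inputs: seeded nucleotide sequences and analytic test signals.

The published experiments ran on the interferon alpha 17 gene (n = 980
base pairs) and a 5000-bp Drosophila gene fragment, but neither sequence
is printed; the presets here are seeded random stand-ins at matching
length and 50% GC content, clearly labelled as such.  Sequence generation
uses numpy's PCG64 generator so identical specs reproduce identical
sequences on every platform; the algorithm identifier is recorded in the
spec itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .observables import ObservableSeries

__all__ = [
    "SequenceSpec",
    "random_sequence",
    "damped_cosine_signal",
    "interferon_like",
    "drosophila_like",
]

KINDS = (
    "random",
    "homopolymer-A",
    "homopolymer-G",
    "alternating-AT",
    "alternating-GC",
)


@dataclass(frozen=True)
class SequenceSpec:
    """Recipe for a reproducible synthetic sequence.

    ``gc_fraction`` is the expected proportion of G+C in ``random`` kind
    (the deterministic kinds ignore it); ``seed`` feeds a PCG64 generator.
    """

    n: int
    gc_fraction: float = 0.5
    seed: int = 0
    kind: str = "random"
    rng_algorithm: str = "numpy-PCG64"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("sequence length must be >= 2")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.kind not in KINDS:
            raise ValueError(f"unknown sequence kind {self.kind!r}")


def random_sequence(spec: SequenceSpec) -> str:
    """Generate the sequence described by ``spec`` (deterministic per spec)."""
    n = spec.n
    if spec.kind == "homopolymer-A":
        return "A" * n
    if spec.kind == "homopolymer-G":
        return "G" * n
    if spec.kind == "alternating-AT":
        return ("AT" * (n // 2 + 1))[:n]
    if spec.kind == "alternating-GC":
        return ("GC" * (n // 2 + 1))[:n]
    rng = np.random.default_rng(spec.seed)
    is_gc = rng.random(n) < spec.gc_fraction
    # uniform choice within the strong/weak pair keeps both strands unbiased
    flip = rng.random(n) < 0.5
    strong = np.where(flip, "G", "C")
    weak = np.where(flip, "A", "T")
    return "".join(np.where(is_gc, strong, weak))


def interferon_like(seed: int = 17) -> SequenceSpec:
    """Synthetic stand-in for the interferon alpha 17 gene: n = 980, 50% GC.

    The real gene sequence is not bundled; this is a seeded random surrogate
    of matching length.
    """
    return SequenceSpec(n=980, gc_fraction=0.5, seed=seed)


def drosophila_like(seed: int = 28) -> SequenceSpec:
    """Synthetic stand-in for the 5000-bp Drosophila gene fragment."""
    return SequenceSpec(n=5000, gc_fraction=0.5, seed=seed)


def damped_cosine_signal(
    gamma: float,
    omega: float,
    amplitude: float = 1.0,
    offset: float = 0.0,
    times: np.ndarray | None = None,
) -> ObservableSeries:
    """Analytic damped oscillation ``offset + amplitude e^(-gamma t) cos(omega t)``.

    Ground-truth input for validating envelope extraction and decay-rate
    fitting (``gamma`` in 1/s, ``omega`` in rad/s).
    """
    if times is None:
        # ~40 samples per period over ~4 decay times
        span = 4.0 / gamma if gamma > 0 else 40.0 * 2.0 * np.pi / omega
        n = max(1000, int(span * omega / (2.0 * np.pi) * 40))
        times = np.linspace(0.0, span, min(n, 2_000_000))
    times = np.asarray(times, dtype=float)
    values = offset + amplitude * np.exp(-gamma * times) * np.cos(omega * times)
    return ObservableSeries(times=times, values=values, label="damped_cosine")
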