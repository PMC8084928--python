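"""Coil combination and echo phase referencing.

Per-coil complex echo volumes are collapsed to one magnitude and one phase
volume per echo, then the phase of the shortest echo is subtracted so that
later stages see only the phase *evolution* between echoes.  The water-fat
solver therefore operates on effective echo times ``tau_n = t_n - t_1``
with complex species amplitudes absorbing the echo-1 phase.

Two phase-combination modes are provided:

``phase_sum``
    The per-voxel sum of the phase angles of every coil, wrapped.  Note
    that when all coils see the same object phase this *multiplies* the
    echo-to-echo phase evolution by the number of coils, so it is only
    meaningful for single-coil data or for studying that very artefact.
``complex_sum``
    The phase of the coil-summed complex signal.  This preserves the
    object phase for any coil count and is the pipeline default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MultiEchoComplexImage",
    "CombinedEchoImage",
    "wrap_phase",
    "combine_coils",
    "reference_to_first_echo",
]


def wrap_phase(phi: np.ndarray | float) -> np.ndarray:
    """Wrap phase values into the half-open interval (-pi, pi]."""
    out = np.mod(np.asarray(phi, dtype=np.float64), 2.0 * np.pi)
    return np.where(out > np.pi, out - 2.0 * np.pi, out)


@dataclass
class MultiEchoComplexImage:
    """Per-coil per-echo complex volumes on one grid."""

    data: np.ndarray  # (n_coils, n_echoes, nx, ny, nz) complex
    echo_times_ms: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=np.float64)
        if self.data.ndim != 5:
            raise ValueError("data must be (coil, echo, x, y, z)")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one coil")
        if self.data.shape[1] < 3 or self.echo_times_ms.size != self.data.shape[1]:
            raise ValueError("need >= 3 echoes with matching echo times")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]


@dataclass
class CombinedEchoImage:
    """Coil-combined echoes: magnitude, wrapped phase and relative phase."""

    magnitude: np.ndarray  # (n_echoes, nx, ny, nz), >= 0
    phase: np.ndarray  # wrapped to (-pi, pi]
    echo_times_ms: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    relative_phase: np.ndarray | None = None  # echo-1 referenced, wrapped

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=np.float64)
        self.phase = np.asarray(self.phase, dtype=np.float64)
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=np.float64)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude/phase shape mismatch")

    @property
    def tau_ms(self) -> np.ndarray:
        """Effective echo times ``t_n - t_1`` in ms."""
        return self.echo_times_ms - self.echo_times_ms[0]

    def complex_referenced(self) -> np.ndarray:
        """Complex echoes ``magnitude * exp(i * relative_phase)`` for the solver."""
        if self.relative_phase is None:
            raise ValueError("call reference_to_first_echo first")
        return self.magnitude * np.exp(1j * self.relative_phase)


def combine_coils(multi: MultiEchoComplexImage, mode: str = "phase_sum") -> CombinedEchoImage:
    """Combine coils into per-echo magnitude and phase volumes.

    Magnitude is the root sum of squares over coils in either mode.  Phase
    follows ``mode`` (see module docstring).  Voxels with zero combined
    magnitude get phase 0 by convention.
    """
    if mode not in ("phase_sum", "complex_sum"):
        raise ValueError(f"unknown combination mode {mode!r}")
    magnitude = np.sqrt(np.sum(np.abs(multi.data) ** 2, axis=0))
    if mode == "phase_sum":
        phase = wrap_phase(np.sum(np.angle(multi.data), axis=0))
    else:
        phase = np.angle(np.sum(multi.data, axis=0))
    phase = np.where(magnitude == 0.0, 0.0, phase)
    return CombinedEchoImage(magnitude=magnitude, phase=phase,
                             echo_times_ms=multi.echo_times_ms,
                             spacing_mm=multi.spacing_mm)


def reference_to_first_echo(combined: CombinedEchoImage) -> CombinedEchoImage:
    """Subtract the shortest echo's phase from every echo (wrapped).

    The echo-1 relative phase is identically zero; downstream complex
    echoes are ``magnitude_n * exp(i * (phi_n - phi_1))``.
    """
    rel = wrap_phase(combined.phase - combined.phase[0])
    rel[0] = 0.0
    return replace(combined, relative_phase=rel)
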