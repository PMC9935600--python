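"""Normalization and defect-information embedding for network training.

Projection intensities are normalized to [0, 1] by division by a stack
maximum.  By default the fast and full-time stacks of one subject share the
*full-time* maximum, so the count-level contrast between the two (a fast
stack carries roughly p times the counts) is preserved in the normalized
domain; per-stack self-normalization is available behind a switch.

The binary patient defect flag (0 = without defect, 1 = with defect) is
embedded by appending four constant detector-sized slices to the tail of the
view axis; stripping them recovers the original stack exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .projector import ProjectionStack

__all__ = [
    "TrainingSample", "normalize", "denormalize", "normalize_pair",
    "embed_defect_block", "strip_defect_block", "pad_views", "unpad_views",
    "N_DEFECT_SLICES",
]

#: number of constant slices appended to carry the defect flag
N_DEFECT_SLICES = 4


@dataclass
class TrainingSample:
    """One normalized (fast input, full-time target) projection pair."""

    input_stack: np.ndarray    # in [0, ~1]
    target_stack: np.ndarray   # in [0, 1]
    defect_label: int
    norm_scale: float
    subject_index: int = -1

    def validate(self) -> None:
        if self.norm_scale <= 0:
            raise ValueError("norm_scale must be positive")
        if self.target_stack.max() > 1.0 + 1e-6 or self.target_stack.min() < 0:
            raise ValueError("target stack not normalized to [0, 1]")


def normalize(stack: ProjectionStack | np.ndarray,
              scale: float | None = None) -> tuple[np.ndarray, float]:
    """Divide by the stack maximum (or a caller-supplied shared scale)."""
    arr = stack.counts if isinstance(stack, ProjectionStack) else np.asarray(stack)
    if scale is None:
        scale = float(arr.max())
    if scale <= 0:
        raise ValueError("cannot normalize an all-zero stack")
    return arr / scale, float(scale)


def denormalize(arr: np.ndarray, scale: float) -> np.ndarray:
    if scale <= 0:
        raise ValueError("norm scale must be positive")
    return arr * scale


def normalize_pair(ft: ProjectionStack, fast: ProjectionStack,
                   mode: str = "shared") -> tuple[np.ndarray, np.ndarray, float]:
    """Normalize a (full-time, fast) pair of one subject.

    mode 'shared': both divided by the FT maximum (default); 'per_stack':
    each by its own maximum.  Returns (ft_norm, fast_norm, ft_scale).
    """
    ft_norm, ft_scale = normalize(ft)
    if mode == "shared":
        fast_norm, _ = normalize(fast, scale=ft_scale)
    elif mode == "per_stack":
        fast_norm, _ = normalize(fast)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return ft_norm, fast_norm, ft_scale


def embed_defect_block(stack_array: np.ndarray, defect_label: int,
                       n_slices: int = N_DEFECT_SLICES) -> np.ndarray:
    """Append ``n_slices`` constant slices holding the binary defect flag."""
    if defect_label not in (0, 1):
        raise ValueError(f"defect label must be binary, got {defect_label!r}")
    v, h, w = stack_array.shape
    block = np.full((n_slices, h, w), float(defect_label), dtype=stack_array.dtype)
    return np.concatenate([stack_array, block], axis=0)


def strip_defect_block(stack_array: np.ndarray,
                       n_slices: int = N_DEFECT_SLICES) -> np.ndarray:
    """Inverse of :func:`embed_defect_block`."""
    if stack_array.shape[0] <= n_slices:
        raise ValueError("stack too short to strip a defect block from")
    return stack_array[:-n_slices]


def pad_views(stack_array: np.ndarray, multiple: int) -> tuple[np.ndarray, int]:
    """Zero-pad the view axis at the tail up to a multiple (network stride).

    Returns the padded array and the original view count for
    :func:`unpad_views`.
    """
    v = stack_array.shape[0]
    pad = (-v) % multiple
    if pad == 0:
        return stack_array, v
    padded = np.concatenate(
        [stack_array, np.zeros((pad,) + stack_array.shape[1:], stack_array.dtype)], axis=0)
    return padded, v


def unpad_views(stack_array: np.ndarray, n_views: int) -> np.ndarray:
    return stack_array[:n_views]
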