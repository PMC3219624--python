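"""Shared helpers: error types, seed derivation, group medians."""

from __future__ import annotations

import numpy as np

__all__ = [
    "ParameterError",
    "CapacityError",
    "CalibrationError",
    "ConfigurationError",
    "ReferenceError_",
    "ValidationError",
    "StageError",
    "derive_seed",
]


class ParameterError(ValueError):
    """A parameter is outside its documented domain."""


class CapacityError(RuntimeError):
    """A resource (e.g. tag modules) is exhausted."""


class CalibrationError(RuntimeError):
    """The empirical-null calibration cannot be computed."""


class ConfigurationError(RuntimeError):
    """The dataset lacks something the analysis requires (e.g. unused tags)."""


class ReferenceError_(KeyError):
    """A referenced identifier does not exist."""


class ValidationError(ValueError):
    """An input table fails schema or referential-integrity checks."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(seed: int, stage: str) -> int:
    """Deterministically expand a global seed into a per-stage seed (< 2**31).

    Uses SeedSequence with the stage name folded in, so stages draw
    independent streams while the whole run stays reproducible from one
    integer.
    """
    salt = [ord(c) for c in stage]
    ss = np.random.SeedSequence([int(seed)] + salt)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
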