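"""Shared helpers: exceptions and seeded random substreams."""

from __future__ import annotations

import zlib

import numpy as np


class RapPhrError(Exception):
    """Base class for package errors."""


class AlphabetError(RapPhrError, ValueError):
    """Sequence contains characters outside the allowed alphabet."""


class ConfigError(RapPhrError, ValueError):
    """Invalid configuration or parameter combination."""


class CoordinateError(RapPhrError, ValueError):
    """Genomic coordinates fall outside their contig."""


class InputError(RapPhrError, ValueError):
    """Malformed or inconsistent user input."""


class UndefinedScoreError(RapPhrError, ValueError):
    """A score is requested on input for which it is not defined."""


class NewickParseError(RapPhrError, ValueError):
    """Newick text could not be parsed.

    Attributes
    ----------
    position : int or None
        0-based character offset of the first detected problem.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a named, reproducible random substream derived from one seed.

    Every source of randomness in the package draws from a substream keyed by
    a module/operation name, so that a single pipeline seed reproduces every
    stage independently of execution order.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
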