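"""Shared helpers: seeded RNG streams and error types."""

from __future__ import annotations

import zlib

import numpy as np


class PdprogError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(PdprogError):
    """Invalid configuration value or combination."""


class RangeError(PdprogError):
    """A raw value lies outside its scale's fixed range."""


class DegenerateScaleError(PdprogError):
    """A scale has zero baseline variance in some cohort."""


class CollinearityError(PdprogError):
    """A design matrix is rank deficient."""


class PipelineError(PdprogError):
    """A pipeline stage cannot proceed."""


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Return a named child RNG stream derived from one master seed.

    Streams are independent across names, so adding draws in one stage
    cannot shift the draws of another.  The name is hashed with CRC32,
    which is stable across platforms and sessions.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
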