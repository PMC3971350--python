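"""Exception hierarchy.

All odscore errors derive from :class:`OdscoreError` so callers (and the CLI)
can distinguish validation problems, bad method parameters and degenerate
genes from generic failures.
"""


class OdscoreError(Exception):
    """Base class for all odscore errors."""


class ValidationError(OdscoreError, ValueError):
    """Malformed input: bad matrix shape, duplicate/unknown identifiers,
    missing or non-numeric values, inconsistent covariate tables."""


class ParameterError(OdscoreError, ValueError):
    """A method parameter outside its valid range (e.g. k not in [1, m-1])."""


class DegenerateGeneError(OdscoreError, ValueError):
    """A gene row with zero scale (sd or MAD), or a sample with all-zero
    weights, encountered under degenerate policy 'error'."""
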