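"""Exception hierarchy.

``ValidationError`` covers malformed inputs and configuration (CLI exit
code 2); the remaining exceptions signal computational failures (exit 1).
"""


class ProtonselError(Exception):
    """Base class for all package errors."""


class ValidationError(ProtonselError, ValueError):
    """Invalid input, configuration or precondition violation."""


class DegenerateInputError(ProtonselError, ValueError):
    """Input is structurally valid but the quantity is undefined on it
    (e.g. overlap percentages of an empty organ mask)."""


class SingularFitError(ProtonselError, ValueError):
    """Rank-deficient regression design; names the OAR/margin cell."""


class DegenerateResponseError(ProtonselError, ValueError):
    """Zero-variance regression response: R^2 is undefined."""


class SelectionError(ProtonselError, ValueError):
    """No successfully fitted model available to select from."""


class MissingDoseError(ProtonselError, ValueError):
    """An NTCP model needs a D_mean for an organ that has no dose and no
    missing-organ policy allows imputation."""
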