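"""Exception and warning types shared across the package."""


class KoalaPKError(Exception):
    """Base class for all computational and validation errors."""


class ValidationError(KoalaPKError):
    """Input data violate a structural invariant (lengths, ordering, signs)."""


class TooFewPointsError(KoalaPKError):
    """Not enough quantifiable observations for the requested fit."""


class NonDecliningTerminalError(KoalaPKError):
    """No candidate terminal point set has a negative log-linear slope."""


class AllBLQError(KoalaPKError):
    """Every observation is below the limit of quantification."""


class NonPositiveResidualError(KoalaPKError):
    """Back-extrapolated terminal line does not exceed a pre-peak observation."""


class UnreliableAbsorptionError(KoalaPKError):
    """Estimated absorption rate does not exceed the elimination rate."""


class DegenerateModelError(KoalaPKError):
    """ka == ke: the first-order absorption model is degenerate."""


class NoDepletionError(KoalaPKError):
    """Raised when a depletion-dependent quantity is requested without depletion."""


class KoalaPKWarning(UserWarning):
    """Non-fatal analysis warning (thin fits, auto-corrections)."""
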