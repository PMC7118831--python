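"""Exception hierarchy for waftest."""


class WafError(ValueError):
    """Base class for all waftest errors."""


class DegenerateTraitError(WafError):
    """Trait vector is constant (or otherwise uninformative)."""


class DegenerateVariantError(WafError):
    """A genotype column has zero sample variance, so its score cannot be
    standardized."""


class CollinearityError(WafError):
    """Covariate matrix is rank deficient after adding an intercept."""


class FitFailureError(WafError):
    """Null-model fit did not converge (e.g. separation in the logistic
    fit)."""


class AlignmentError(WafError):
    """Subject identifiers are inconsistent across input files."""


class ConfigError(WafError):
    """Invalid scenario or command-line configuration."""
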