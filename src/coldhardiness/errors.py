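"""Exception types shared across the package."""


class ColdHardinessError(Exception):
    """Base class for all package-specific errors."""


class DataError(ColdHardinessError, ValueError):
    """Malformed, missing or inconsistent input data (gaps, duplicates, NaNs)."""


class ParameterError(ColdHardinessError, ValueError):
    """A model parameter or configuration value violates its invariants."""


class HardinessNotDeterminedError(ColdHardinessError, ValueError):
    """No freezing-test temperature satisfied the damage threshold, so LT10
    cannot be assigned for that sampling date (a censored observation)."""
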