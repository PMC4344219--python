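"""Exception hierarchy for cvregion."""


class CVRegionError(Exception):
    """Base class for all cvregion errors."""


class ConfigError(CVRegionError):
    """A configuration problem: missing column, bad variable declaration, ..."""


class DataError(CVRegionError):
    """A data problem: non-numeric cell, duplicate id, invalid geometry, ..."""


class InfeasibleError(CVRegionError):
    """No feasible partition exists under the given constraints.

    Raised when every randomized construction attempt fails; the usual remedy
    is to relax the CV target or the population bounds.
    """
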