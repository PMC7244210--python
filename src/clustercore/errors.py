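"""Exception and warning types shared across the package."""


class ClustercoreError(Exception):
    """Base class for all errors raised by clustercore."""


class GPRParseError(ClustercoreError):
    """A gene-protein-reaction rule could not be parsed."""


class GPRExpansionError(ClustercoreError):
    """DNF expansion of a GPR exceeded the clause cap."""


class InputError(ClustercoreError):
    """Invalid or inconsistent user input (files, matrices, parameters)."""


class DegenerateDataWarning(UserWarning):
    """A numerical degeneracy was handled by a documented fallback.

    Raised e.g. when every cluster standard deviation equals the dataset
    standard deviation, when all raw thresholds coincide, or when no
    enzyme lies below threshold anywhere (all ubiquity scores 1).
    """
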