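"""Exception hierarchy shared across seedmod modules."""


class SeedmodError(Exception):
    """Base class for all seedmod errors."""


class InputError(SeedmodError):
    """Malformed or inconsistent input data."""


class ParseError(InputError):
    """A file could not be parsed; the message names the offending cell."""


class SeedNotInUniverseError(SeedmodError):
    """The requested seed gene is absent from the harmonized gene universe.

    Distinct from module-discovery failure: discovery failure means the
    seed is present but no feasible module exists under the constraints.
    """
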