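"""Exception hierarchy shared across the package."""


class PetsvError(Exception):
    """Base class for all package errors."""


class InputError(PetsvError):
    """Malformed or inconsistent user input (CLI exit code 2)."""


class InvariantError(PetsvError):
    """An internal invariant was violated (CLI exit code 3)."""
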