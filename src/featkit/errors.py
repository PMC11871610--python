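"""Exception hierarchy shared across featkit modules."""


class FeatkitError(Exception):
    """Base class for all featkit errors."""


class FormatError(FeatkitError):
    """A file does not conform to its declared format."""


class QCError(FeatkitError):
    """Structure quality control failed in strict mode.

    Carries ``unk_positions``: the (chain, author_number) pairs of
    unknown residues that triggered the failure.
    """

    def __init__(self, message, unk_positions=None):
        super().__init__(message)
        self.unk_positions = list(unk_positions or [])


class DistanceUndefinedError(FeatkitError):
    """A residue lacks the atom(s) required by the chosen distance metric."""
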