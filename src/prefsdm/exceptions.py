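"""Exception hierarchy shared by all prefsdm modules."""


class PrefsdmError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(PrefsdmError, ValueError):
    """A caller supplied an invalid argument (bad domain, shape, sign...)."""


class FormatError(PrefsdmError, ValueError):
    """A file on disk does not conform to the declared text format."""


class CapabilityError(PrefsdmError, RuntimeError):
    """A requested computation path cannot handle the problem size."""


class ConvergenceError(PrefsdmError, RuntimeError):
    """An iterative fit failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
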