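"""Exception hierarchy shared across the package."""


class ChromatexError(Exception):
    """Base class for all package-specific errors."""


class UnsupportedFormatError(ChromatexError):
    """Image file is readable but not 8-bit gray or 8-bit/channel RGB."""


class EmptyMaskError(ChromatexError):
    """A mask with no foreground pixels."""


class MultiComponentMaskError(ChromatexError):
    """A mask whose foreground splits into more than one 8-connected component."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"mask foreground has {n_components} 8-connected components; expected 1"
        )


class DimensionError(ChromatexError):
    """Image/mask shape mismatch."""


class ConfigurationError(ChromatexError):
    """Invalid parameter value (unknown method name, bad level count, ...)."""


class DegenerateMatrixError(ChromatexError):
    """Co-occurrence matrix with no valid pixel pair."""


class DegenerateFitError(ChromatexError):
    """Log-log regression cannot be fitted (no variance in the abscissa)."""


class DegenerateTestError(ChromatexError):
    """A statistical test whose variance term is exactly zero."""


class InsufficientDataError(ChromatexError):
    """Too few observations for the requested test."""
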