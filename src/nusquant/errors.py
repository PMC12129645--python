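"""Exception hierarchy shared across the package."""


class NusquantError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NusquantError, ValueError):
    """A caller-supplied parameter is out of its documented domain."""


class FormatError(NusquantError, ValueError):
    """A serialized artefact (nuslist, CSV, config) violates its format."""


class NormalizationError(NusquantError, ValueError):
    """PANIC normalization is undefined for the supplied integrals."""


class ReferenceError_(NusquantError, ValueError):
    """The reference build-up curve is unusable, so no distance can be referenced."""
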