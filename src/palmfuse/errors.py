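"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateExtremaError(RuntimeError):
    """Too few strict extrema to derive an order-statistics filter window.

    Raised by the window-selection primitives; :func:`palmfuse.fabemd.decompose`
    catches it internally and falls back to an early stop (zero BIMFs for the
    remaining levels).
    """


class NoDiscriminativeInformationError(RuntimeError):
    """The weighted between-class scatter vanished; no fusion direction exists."""
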