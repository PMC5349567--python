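"""Exception types raised on invalid inputs or undefined quantities."""


class ValidationError(ValueError):
    """An input violates a structural invariant (bad tree, table, or mapping)."""


class UndefinedQuantityError(ValueError):
    """The requested quantity is mathematically undefined for this input
    (e.g. beta diversity with a single group, turnover when H(G) = 0)."""
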