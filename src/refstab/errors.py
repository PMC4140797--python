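"""Exception types shared across the package."""


class RefstabError(ValueError):
    """Base class for all refstab errors."""


class FormatError(RefstabError):
    """A file violates the expected on-disk layout (duplicate labels,
    non-numeric cells, broken table fences)."""


class InputError(RefstabError):
    """Structurally valid input that an operation cannot accept
    (missing CT values, too few genes/samples, unknown time points)."""
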