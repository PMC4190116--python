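"""Exception types shared across the pipeline.

``ValidationError`` marks bad inputs or configuration (CLI exit code 1);
anything else propagating out of a stage is a runtime failure (exit code 2).
"""


class PollenidError(Exception):
    """Base class for pipeline errors."""


class ValidationError(PollenidError):
    """Invalid input data, file format or configuration."""
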