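"""Exception hierarchy.

``ConfigError`` marks bad user-supplied configuration (CLI exit code 2);
``ValidationError`` marks malformed input data; everything else that the
package raises deliberately derives from ``SeptimarkError`` (exit code 1).
"""


class SeptimarkError(Exception):
    """Base class for all errors raised deliberately by septimark."""


class ConfigError(SeptimarkError):
    """A parameter or configuration value is outside its documented domain."""


class ValidationError(SeptimarkError):
    """Input data violates a documented invariant."""
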