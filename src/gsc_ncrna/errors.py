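class FormatError(ValueError):
    """Malformed input file or record (data error, CLI exit code 1)."""


class ConfigError(ValueError):
    """Invalid configuration or missing required companion data (exit code 2)."""
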