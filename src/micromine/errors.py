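"""Package exceptions."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""
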