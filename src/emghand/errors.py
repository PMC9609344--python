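"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """A parameter is outside its admissible range (bad cutoff, fraction, rate...)."""


class ProtocolError(RuntimeError):
    """An acquisition protocol requirement is violated (e.g. class shortfall)."""
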