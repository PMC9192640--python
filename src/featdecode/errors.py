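"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """Invalid or infeasible configuration (counterbalancing, timing, codes)."""


class FormatError(ValueError):
    """A file did not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """Data violated a semantic invariant (enum codes, labelling consistency)."""


class DegeneratePopulationError(ValueError):
    """A normalisation population had zero variance."""
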