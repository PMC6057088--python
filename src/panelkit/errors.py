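"""Exception hierarchy shared across the pipeline stages."""


class PanelkitError(Exception):
    """Base class for all panelkit-specific failures."""


class InvalidConfigError(PanelkitError):
    """A configuration object violates its invariants."""


class InsufficientDataError(PanelkitError):
    """Not enough observations to compute the requested statistic."""


class EmptyMaskError(PanelkitError):
    """A site-selection step produced no eligible sites."""


class EmptyPanelError(PanelkitError):
    """Panel subsetting removed every sample or every site."""


class NoDonorsError(PanelkitError):
    """The copying model was given an empty donor set."""


class SiteMismatchError(PanelkitError):
    """Typed sites (or panel sites) do not line up between two inputs."""


class UnphasedInputError(PanelkitError):
    """Diploid input with heterozygous calls but no phase information."""


class DegenerateInputError(PanelkitError):
    """Input matrix carries no usable variation (e.g. constant genotypes)."""


class FormatError(PanelkitError):
    """A file does not conform to the expected dialect."""
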