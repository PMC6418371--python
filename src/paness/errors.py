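"""Exception hierarchy for the pipeline.

Per-record problems during a scan are collected into the run summary rather
than raised; these exceptions cover contract violations and unusable inputs.
"""


class PanessError(Exception):
    """Base class for all pipeline errors."""


class VcfParseError(PanessError):
    """Malformed VCF header or record."""


class GeneModelError(PanessError):
    """Gene/transcript model violates its invariants or cannot be parsed."""


class ContextWindowError(PanessError):
    """A requested sequence window falls outside chromosome bounds."""


class AnnotationError(PanessError):
    """A frequency or score annotation could not be interpreted."""


class ConfigurationError(PanessError):
    """Invalid filter/pipeline configuration (bad comparator, missing role...)."""


class ConsequenceError(PanessError):
    """Exon-skip consequence cannot be computed (no CDS, bad frame, ...)."""


class FixtureError(PanessError):
    """Synthetic-fixture generation failed (no room to place a feature...)."""
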