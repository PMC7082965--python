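"""Named exceptions raised across the pipeline stages."""


class CoexnetError(Exception):
    """Base class for all coexnet errors."""


class ValidationError(CoexnetError, ValueError):
    """Malformed or inconsistent input data."""


class DETableError(ValidationError):
    """A differential-expression table violates its contract."""


class ConstantGeneError(ValidationError):
    """Zero-variance gene rows make Pearson correlation undefined."""

    def __init__(self, gene_ids):
        self.gene_ids = list(gene_ids)
        super().__init__(
            f"{len(self.gene_ids)} gene(s) have constant expression across "
            f"samples: {', '.join(map(str, self.gene_ids[:10]))}"
            + ("…" if len(self.gene_ids) > 10 else "")
        )


class DegenerateFitError(CoexnetError):
    """Scale-free fit impossible (e.g. all connectivities identical)."""


class PartitionMismatchError(ValidationError):
    """Two partitions do not cover the same item set."""

    def __init__(self, only_first, only_second):
        self.only_first = sorted(only_first)
        self.only_second = sorted(only_second)
        super().__init__(
            "partitions cover different items: "
            f"{len(self.only_first)} only in first "
            f"(e.g. {self.only_first[:5]}), "
            f"{len(self.only_second)} only in second "
            f"(e.g. {self.only_second[:5]})"
        )


class PipelineError(CoexnetError):
    """Fatal condition while orchestrating a full run."""
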