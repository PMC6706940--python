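"""Exception hierarchy for cpeparch."""


class CpepArchError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CpepArchError):
    """A configuration value is missing, non-finite or out of range."""


class MissingMetadataError(CpepArchError):
    """Summary-statistic records lack per-SNP metadata (MAF / info)."""

    def __init__(self, snp_ids):
        self.snp_ids = list(snp_ids)
        super().__init__(
            f"{len(self.snp_ids)} SNP(s) without metadata: "
            + ", ".join(map(str, self.snp_ids[:10]))
            + ("..." if len(self.snp_ids) > 10 else "")
        )


class AlignmentError(CpepArchError):
    """Individuals or SNPs do not line up between two inputs."""


class AlleleCodeError(CpepArchError):
    """An HLA allele code is not a 4-digit string."""
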