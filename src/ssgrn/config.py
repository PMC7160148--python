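"""Run configuration for the two-stage reaction-norm GWAS pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class RunConfig:
    """Constants governing a pipeline run.

    Parameters
    ----------
    ec_levels
        Environment levels (sd units of the standardized gradient) at which
        SNP effects are projected and tested.  Defaults to the Low / Medium /
        High convention of -3, 0, +3 sd.
    legendre_order
        Order of the Legendre basis for the reaction norm (1 = intercept +
        slope).
    sig_threshold_neglog10p
        A SNP is declared significant when -log10(p) exceeds this value.
    fdr_level
        Level for Benjamini-Hochberg control in enrichment tests and for the
        q-values reported alongside the fixed threshold.
    window_bp
        Flank size (bp) around a significant SNP when mapping genes/QTL.
    accuracy_min
        Minimum per-coefficient breeding-value accuracy for an animal to
        enter SNP back-solving.
    blend_weight
        Weight on the genomic relationship matrix when blending with the
        pedigree submatrix before inversion (1.0 = no blending).
    rng_seed
        Seed for every stochastic step of a run.
    """

    ec_levels: list[float] = field(default_factory=lambda: [-3.0, 0.0, 3.0])
    legendre_order: int = 1
    sig_threshold_neglog10p: float = 6.0
    fdr_level: float = 0.05
    window_bp: int = 200_000
    accuracy_min: float = 0.40
    blend_weight: float = 0.95
    rng_seed: int = 2026

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if any(abs(e) > 3.0 for e in self.ec_levels):
            raise ValueError("ec_levels must lie within [-3, 3]")
        if not 0.0 < self.fdr_level < 1.0:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if not 0.0 < self.blend_weight <= 1.0:
            raise ValueError("blend_weight must be in (0, 1]")
        if self.legendre_order < 0:
            raise ValueError("legendre_order must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        """Load a config from a TOML or YAML file (chosen by extension)."""
        import pathlib

        p = pathlib.Path(path)
        if p.suffix == ".toml":
            import tomllib

            with open(p, "rb") as fh:
                return cls.from_dict(tomllib.load(fh))
        if p.suffix in (".yaml", ".yml"):
            import yaml

            with open(p) as fh:
                return cls.from_dict(yaml.safe_load(fh))
        raise ValueError(f"unrecognised config format: {p.suffix}")
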