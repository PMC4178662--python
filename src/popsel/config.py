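"""Run configuration: every tunable threshold of every stage, with
defaults at the analysis' published operating point, serializable to and
from a flat ``key = value`` text file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

from .filters import FilterConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # genotype filters
    qual_min: float = 90.0
    dp_min: int = 20
    dp_max: int = 60
    pl_best_max: int = 0
    pl_second_min: int = 40
    region_window: int = 20_000
    region_min_frac: float = 0.30
    # IBD and downsampling
    ibd_window: int = 200_000
    fis_threshold: float = 0.5
    ibd_min_sites: int = 50
    target_n: int = 23
    downsample: str = "stochastic"
    # site classes
    junction_bp: int = 30
    # divergence
    mask_flank: int = 5
    fixed_min_chromosomes: int = 20
    # DFE / alpha
    dfe_bin_edges: tuple = (0.0, 1.0, 10.0, 100.0, float("inf"))
    block_size: int = 10_000
    dfe_bootstrap_reps: int = 200
    matrix_n: int = 100
    # sweep scan
    sweep_window: int = 1000
    sweep_window_sizes: tuple = (500, 1000, 2000)
    sweep_span: int = 40_000
    sweep_reps: int = 1000
    sweep_trim: int = 25
    # expression
    min_fpkm: float = 1.0
    n_expression_bins: int = 4
    expression_bootstrap_reps: int = 1000
    dnds_permutations: int = 10_000
    # reproducibility
    seed: int = 1

    @property
    def filters(self) -> FilterConfig:
        return FilterConfig(
            qual_min=self.qual_min, dp_min=self.dp_min, dp_max=self.dp_max,
            pl_best_max=self.pl_best_max,
            pl_second_min=self.pl_second_min,
            region_window=self.region_window,
            region_min_frac=self.region_min_frac,
            ibd_window=self.ibd_window,
            fis_threshold=self.fis_threshold,
            ibd_min_sites=self.ibd_min_sites, target_n=self.target_n,
            downsample=self.downsample)

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(str(x) for x in v)
                fh.write(f"{f.name} = {v}\n")

    @classmethod
    def from_text(cls, path) -> "RunConfig":
        raw = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                k, v = (s.strip() for s in line.split("=", 1))
                raw[k] = v
        kwargs = {}
        for f in fields(cls):
            if f.name not in raw:
                continue
            v = raw[f.name]
            if f.name in ("dfe_bin_edges", "sweep_window_sizes"):
                kwargs[f.name] = tuple(float(x) if "." in x or x == "inf"
                                       else int(x) for x in v.split(","))
            elif f.type == "int":
                kwargs[f.name] = int(v)
            elif f.type == "float":
                kwargs[f.name] = float(v)
            else:
                kwargs[f.name] = v
        return cls(**kwargs)

    def digest(self) -> str:
        import hashlib
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
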