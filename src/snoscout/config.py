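"""Pipeline configuration.

All tunables of the candidate-search workflows live here, with the defaults
used throughout the package. A flat ``key = value`` text file (keys written
with dots, e.g. ``haca.gap_tol = 3``) can override any field; command-line
flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path


@dataclass
class PipelineConfig:
    # H/ACA candidate search
    haca_max_h_aca_distance: int = 120   # max nt between H box end and ACA start
    haca_upstream_window: int = 120      # window searched for the candidate start
    haca_gap_tol: int = 3                # max nt between local-fold 3' end and H box
    haca_min_stem_bp: int = 3            # minimum pairs per hairpin
    haca_constraint_offset: int = 14     # the constrained base upstream of each box

    # C/D candidate search
    cd_max_c_d_span: int = 200           # C box start -> D box end
    cd_flank: int = 20                   # flanking nt folded with the candidate
    cd_min_stem_bp: int = 3              # minimum terminal-stem pairs

    # shuffled-ensemble statistics
    n_shuffles: int = 100

    # engines and reporting
    folding_engine: str = "vienna"
    report_cutoff: float = 0.5
    seed: int = 0

    # SVM protocol
    svm_folds: int = 10
    grid_min_exp: int = -15
    grid_max_exp: int = 15

    def grid_exponents(self) -> range:
        return range(self.grid_min_exp, self.grid_max_exp + 1)


_KEYMAP = {f.name.replace("_", ".", 1) if f.name.startswith(("haca_", "cd_", "svm_"))
           else f.name: f.name for f in fields(PipelineConfig)}
# also accept plain underscore keys
_KEYMAP.update({f.name: f.name for f in fields(PipelineConfig)})
_KEYMAP["folding.engine"] = "folding_engine"


def load_config(path, base: PipelineConfig | None = None) -> PipelineConfig:
    """Read a flat key/value config file on top of ``base`` (or defaults)."""
    cfg = base or PipelineConfig()
    overrides = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _KEYMAP:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        name = _KEYMAP[key]
        current = getattr(cfg, name)
        if isinstance(current, bool):
            overrides[name] = value.lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            overrides[name] = int(value)
        elif isinstance(current, float):
            overrides[name] = float(value)
        else:
            overrides[name] = value
    return replace(cfg, **overrides)
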