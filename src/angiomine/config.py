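"""Run configuration: YAML-loadable, unknown keys rejected, echoed in reports."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    species: str = "human"
    threshold_override: float | None = None
    threshold_housekeeping: tuple[str, ...] | None = None
    sd_ddof: int = 1
    ap_denominator: str = "panel"
    cc_median_scope: str = "all"
    tiers_high_cut: float = 0.4
    tiers_low_cut: float = 0.3
    tiers_alpha: float = 0.05
    diff_test: str = "welch"
    diff_d0: float = 4.0
    diff_fdr: str | None = None
    seed: int = 0
    extra: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("extra", None)
        if d.get("threshold_housekeeping") is not None:
            d["threshold_housekeeping"] = list(d["threshold_housekeeping"])
        return d


_NESTED = {
    "threshold": {"override": "threshold_override",
                  "housekeeping": "threshold_housekeeping",
                  "sd_ddof": "sd_ddof"},
    "ap": {"denominator": "ap_denominator"},
    "cc": {"median_scope": "cc_median_scope"},
    "tiers": {"high_cut": "tiers_high_cut", "low_cut": "tiers_low_cut",
              "alpha": "tiers_alpha"},
    "diff": {"test": "diff_test", "d0": "diff_d0", "fdr": "diff_fdr"},
}
_TOP = {"species", "seed"}


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for key, val in raw.items():
        if key in _TOP:
            setattr(cfg, key, val)
        elif key in _NESTED:
            if not isinstance(val, dict):
                raise ValueError(f"config section {key!r} must be a mapping")
            for sub, v in val.items():
                if sub not in _NESTED[key]:
                    raise ValueError(f"unknown config key {key}.{sub}")
                attr = _NESTED[key][sub]
                if attr == "threshold_housekeeping" and v is not None:
                    v = tuple(v)
                setattr(cfg, attr, v)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return cfg
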