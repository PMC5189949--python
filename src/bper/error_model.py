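"""Base-position error rate (BPER) background model.

The calling null of ultra-deep targeted ctDNA sequencing is position-specific:
every (panel position, alteration) pair has its own background error fraction,
estimated from a set of mutation-free control samples.  A candidate variant is
only called when its allele fraction is incompatible with that background.

Model
-----
For control ``i`` with depth ``d_i`` and alteration count ``c_i`` at a pair
(p, a), the smoothed error fraction is

    r_i = (c_i + c0) / (d_i + 4 c0)

with pseudocount ``c0`` (default 0.5, avoiding degenerate zero variance at
clean positions).  The background mean mu and sample standard deviation sigma
are taken over controls with depth >= ``min_depth``; controls showing a
germline-like fraction (r_i > ``germline_cut``) are dropped from that pair's
estimate, and the whole position is masked when more than half the controls
look germline there (a private SNP, not sequencing noise).

The per-pair calling threshold reported by the model is

    tau(p, a) = max(mu + k sigma, floor(a))

where ``k`` (default 3) bounds the position noise and ``floor`` is the
kind-specific validated detection limit of the assay: 0.003 for substitutions
and indels of <= 2 bp, 0.001 for indels of > 2 bp.  How tau enters the calling
decision is the caller's contract (see :mod:`bper.caller`): the noise bound
mu + k sigma is a point condition on the observed allele fraction, while the
floor is compared against the one-sided upper confidence bound of the
measured fraction, so that a variant truly present at the floor is reliably
detected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .caller import CallerConfig, SampleCallResult, call_sample, track_markers
from .exceptions import (
    CalibrationError,
    ConsistencyError,
    MaskedPositionError,
    ModelLookupError,
    ModelVersionError,
)
from .panel import Alteration, PanelPosition, PileupMatrix

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ErrorModelConfig:
    """Calibration settings for the background error model.

    k:            Gaussian multiplier on the control-rate spread (tau = mu + k sigma).
    pseudocount:  additive smoothing c0 on counts (and 4*c0 on depth).
    min_depth:    controls shallower than this are ignored at a position.
    min_controls: minimum number of control samples required to calibrate.
    germline_cut: control error fraction above which a control is considered
                  to carry a germline variant at that position.
    floor_snv / floor_long_indel: validated assay detection limits (allele
                  fraction) for substitutions / short indels and >2 bp indels.
    hotspot_k:    optional reduced multiplier at recurrent hotspot positions.
    """

    k: float = 3.0
    pseudocount: float = 0.5
    min_depth: int = 1000
    min_controls: int = 10
    germline_cut: float = 0.05
    floor_snv: float = 0.003
    floor_long_indel: float = 0.001
    hotspot_k: float | None = None

    def floor_for(self, alteration: Alteration) -> float:
        return self.floor_long_indel if alteration.classify() == "long_indel" else self.floor_snv

    def k_for(self, position: PanelPosition) -> float:
        if position.hotspot and self.hotspot_k is not None:
            return self.hotspot_k
        return self.k


@dataclass(frozen=True)
class NoiseStats:
    """Background statistics of one (position, alteration) pair."""

    n_controls: int
    mu: float
    sigma: float


class BackgroundErrorModel:
    """Per-position background noise model, fitted to control pileups.

    Parameters
    ----------
    controls
        >= ``config.min_controls`` pileup matrices from mutation-free control
        samples, all on the same panel.
    config
        :class:`ErrorModelConfig`; defaults are the package defaults.

    Examples
    --------
    >>> model = BackgroundErrorModel(controls)          # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> res.threshold_for(panel[0], Alteration("sub", "T"))  # doctest: +SKIP
    """

    def __init__(self, controls: list[PileupMatrix], config: ErrorModelConfig | None = None):
        self.config = config or ErrorModelConfig()
        if len(controls) < self.config.min_controls:
            raise CalibrationError(
                f"need >= {self.config.min_controls} controls, got {len(controls)}"
            )
        first = controls[0]
        for c in controls[1:]:
            if not first.same_panel(c):
                raise ConsistencyError(f"control {c.sample_id!r} is not on the same panel")
        self.controls = list(controls)
        self.panel = list(first.positions)

    def fit(self) -> "BackgroundErrorModelResults":
        cfg = self.config
        c0 = cfg.pseudocount
        n_pos = len(self.panel)
        depths = np.stack([c.depth for c in self.controls])  # (n_controls, n_pos)
        eligible = depths >= cfg.min_depth

        # depth-dependent smoothed rate of a zero-count pair, per control x position
        zero_rates = c0 / (depths + 4.0 * c0)

        default_stats: list[NoiseStats] = []
        masked = np.zeros(n_pos, dtype=bool)
        pair_stats: dict[tuple[int, str], NoiseStats] = {}

        for i in range(n_pos):
            el = eligible[:, i]
            n_el = int(el.sum())
            if n_el == 0:
                masked[i] = True
                default_stats.append(NoiseStats(0, 0.0, 0.0))
                continue
            zr = np.sort(zero_rates[el, i])
            default_stats.append(NoiseStats(n_el, float(zr.mean()), _sample_sd(zr)))

            keys = set()
            for c in self.controls:
                keys.update(k for k, v in c.counts[i].items() if v > 0)
            for key in sorted(keys):
                cnt = np.array([c.counts[i].get(key, 0) for c in self.controls], dtype=float)
                r = (cnt[el] + c0) / (depths[el, i] + 4.0 * c0)
                germ = r > cfg.germline_cut
                if germ.sum() > 0.5 * n_el:
                    masked[i] = True
                r_used = np.sort(r[~germ])  # sorted: estimates invariant to control order
                if r_used.size == 0:
                    masked[i] = True
                    continue
                pair_stats[(i, key)] = NoiseStats(
                    int(r_used.size), float(r_used.mean()), _sample_sd(r_used)
                )

        return BackgroundErrorModelResults(
            panel=self.panel,
            config=cfg,
            n_controls=len(self.controls),
            default_stats=default_stats,
            pair_stats=pair_stats,
            masked=masked,
        )


def _sample_sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


class BackgroundErrorModelResults:
    """Fitted background model: per-pair noise statistics and thresholds.

    Behaves like a statsmodels results object: carries the estimates
    (:meth:`noise`, :meth:`threshold_for`), a :meth:`summary`, persistence
    (:meth:`save` / :meth:`load`) and downstream actions (:meth:`call_sample`,
    :meth:`track_markers`, :meth:`plot_noise`).
    """

    def __init__(self, panel, config, n_controls, default_stats, pair_stats, masked):
        self.panel: list[PanelPosition] = list(panel)
        self.config: ErrorModelConfig = config
        self.n_controls: int = n_controls
        self._default: list[NoiseStats] = list(default_stats)
        self._pairs: dict[tuple[int, str], NoiseStats] = dict(pair_stats)
        self.masked: np.ndarray = np.asarray(masked, dtype=bool)
        self._index = {(p.contig, p.pos): i for i, p in enumerate(self.panel)}

    # -- lookups ---------------------------------------------------------
    def index_of(self, position: PanelPosition | tuple[str, int]) -> int:
        key = (position.contig, position.pos) if isinstance(position, PanelPosition) else tuple(position)
        try:
            return self._index[key]
        except KeyError:
            raise ModelLookupError(f"position {key[0]}:{key[1]} is not covered by the model") from None

    def noise(self, position, alteration: Alteration) -> NoiseStats:
        """Background (n, mu, sigma) of a pair; pairs never seen in controls
        fall back to the position's zero-count statistics."""
        i = position if isinstance(position, int) else self.index_of(position)
        return self._pairs.get((i, alteration.key), self._default[i])

    def is_masked(self, position) -> bool:
        i = position if isinstance(position, int) else self.index_of(position)
        return bool(self.masked[i])

    def tau(self, position, alteration: Alteration) -> float:
        i = position if isinstance(position, int) else self.index_of(position)
        st = self.noise(i, alteration)
        return max(st.mu + self.config.k_for(self.panel[i]) * st.sigma, self.config.floor_for(alteration))

    def threshold_for(self, position, alteration: Alteration) -> float:
        """Allele-fraction calling threshold tau(p, a).

        Raises :class:`MaskedPositionError` for masked positions and
        :class:`ModelLookupError` for positions outside the panel.
        """
        i = position if isinstance(position, int) else self.index_of(position)
        if self.masked[i]:
            p = self.panel[i]
            raise MaskedPositionError(f"position {p.contig}:{p.pos} is masked")
        return self.tau(i, alteration)

    def observed_keys(self, i: int) -> list[str]:
        return [k for (j, k) in self._pairs if j == i]

    # -- downstream ------------------------------------------------------
    def call_sample(self, pileup: PileupMatrix, config: CallerConfig | None = None) -> SampleCallResult:
        return call_sample(pileup, self, config)

    def track_markers(self, pileup, markers, config: CallerConfig | None = None) -> SampleCallResult:
        return track_markers(pileup, self, markers, config)

    # -- reporting -------------------------------------------------------
    def noise_table(self):
        """Per-(position, alteration) background statistics as a DataFrame."""
        import pandas as pd

        rows = []
        for (i, key), st in sorted(self._pairs.items()):
            p = self.panel[i]
            alt = Alteration.from_key(key)
            rows.append(
                {
                    "contig": p.contig,
                    "pos": p.pos,
                    "gene": p.gene,
                    "alteration": key,
                    "n_controls": st.n_controls,
                    "mu": st.mu,
                    "sigma": st.sigma,
                    "tau": self.tau(i, alt),
                    "masked": bool(self.masked[i]),
                }
            )
        return pd.DataFrame(
            rows,
            columns=["contig", "pos", "gene", "alteration", "n_controls", "mu", "sigma", "tau", "masked"],
        )

    def summary(self) -> str:
        mus = np.array([st.mu for st in self._pairs.values()]) if self._pairs else np.array([0.0])
        lines = [
            "Background error model (BPER)",
            "=============================",
            f"panel positions:        {len(self.panel)}",
            f"control samples:        {self.n_controls}",
            f"masked positions:       {int(self.masked.sum())}",
            f"observed (p,a) pairs:   {len(self._pairs)}",
            f"mu quantiles (observed pairs): "
            f"median={np.median(mus):.3g}  p90={np.quantile(mus, 0.9):.3g}  max={mus.max():.3g}",
            f"config: k={self.config.k}  c0={self.config.pseudocount}  min_depth={self.config.min_depth}  "
            f"floors: snv/short={self.config.floor_snv}  long_indel={self.config.floor_long_indel}",
        ]
        return "\n".join(lines)

    def plot_noise(self, ax=None):
        """Background mean error fraction per position, with thresholds."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        pos = np.arange(len(self.panel))
        best_mu = np.array(
            [max((self._pairs[(i, k)].mu for k in self.observed_keys(i)), default=self._default[i].mu)
             for i in pos]
        )
        ax.semilogy(pos, np.maximum(best_mu, 1e-7), ".", ms=2, label="max background mu")
        ax.axhline(self.config.floor_snv, ls="--", c="C1", label="SNV floor")
        ax.axhline(self.config.floor_long_indel, ls=":", c="C2", label=">2 bp indel floor")
        ax.set_xlabel("panel position index")
        ax.set_ylabel("error fraction")
        ax.legend(fontsize=8)
        return ax

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "schema_version": SCHEMA_VERSION,
            "config": asdict(self.config),
            "n_controls": self.n_controls,
            "panel": [
                [p.contig, p.pos, p.ref_base, p.gene, p.hotspot] for p in self.panel
            ],
            "default_stats": [[st.n_controls, st.mu, st.sigma] for st in self._default],
            "pair_stats": [
                [i, key, st.n_controls, st.mu, st.sigma] for (i, key), st in sorted(self._pairs.items())
            ],
            "masked": [int(i) for i in np.flatnonzero(self.masked)],
        }
        with open(path, "wt", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "BackgroundErrorModelResults":
        with open(path, "rt", encoding="utf-8") as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ModelVersionError(f"unreadable model file {path}: {exc}") from None
        if payload.get("schema_version") != SCHEMA_VERSION:
            raise ModelVersionError(
                f"model schema {payload.get('schema_version')!r} != supported {SCHEMA_VERSION}"
            )
        panel = [PanelPosition(c, p, r, g, bool(h)) for c, p, r, g, h in payload["panel"]]
        masked = np.zeros(len(panel), dtype=bool)
        masked[payload["masked"]] = True
        return cls(
            panel=panel,
            config=ErrorModelConfig(**payload["config"]),
            n_controls=payload["n_controls"],
            default_stats=[NoiseStats(n, mu, sd) for n, mu, sd in payload["default_stats"]],
            pair_stats={
                (i, key): NoiseStats(n, mu, sd) for i, key, n, mu, sd in payload["pair_stats"]
            },
            masked=masked,
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, BackgroundErrorModelResults):
            return NotImplemented
        return (
            self.panel == other.panel
            and self.config == other.config
            and self.n_controls == other.n_controls
            and self._default == other._default
            and self._pairs == other._pairs
            and bool((self.masked == other.masked).all())
        )


def calibrate(controls: list[PileupMatrix], config: ErrorModelConfig | None = None) -> BackgroundErrorModelResults:
    """Fit the background model in one step (``BackgroundErrorModel(...).fit()``)."""
    return BackgroundErrorModel(controls, config).fit()
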