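"""Study orchestration: fit the full agreement analysis on a paired cohort.

`HRVAgreementStudy` is the model object: it holds the paired recordings,
the preprocessing configuration and the segmentation scheme.  `fit()`
computes the six HRV endpoints for every subject x device x window and
assembles the agreement tables; the result object carries them and knows
how to summarise and export itself.

Two families of comparisons are produced, mirroring the validation design:

* segment vs. the 0-5-minute standard, within device, paired across
  subjects (is a shorter window a surrogate for the 5-minute criterion?);
* reference vs. test device, within segment (does the chest-strap-derived
  series agree with the ECG-derived one?).
"""

from __future__ import annotations

import io
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .agreement import compare
from .metrics import FREQ_DOMAIN, METRIC_NAMES, TIME_DOMAIN, compute_metrics
from .preprocess import PreprocessConfig
from .rr import Recording, RRSeries, read_rr
from .segmentation import STANDARD_LABEL, SegmentSpec, default_scheme, extract

__all__ = ["HRVAgreementStudy", "StudyResults"]

log = logging.getLogger(__name__)


def _pair_up(recordings) -> dict[str, tuple[Recording, Recording]]:
    """Group a flat or pre-paired recording list into subject pairs."""
    flat: list[Recording] = []
    for item in recordings:
        if isinstance(item, Recording):
            flat.append(item)
        else:
            flat.extend(item)
    by_subject: dict[str, dict[str, Recording]] = {}
    for rec in flat:
        by_subject.setdefault(rec.subject_id, {})[rec.device] = rec
    pairs: dict[str, tuple[Recording, Recording]] = {}
    for sid in sorted(by_subject):
        devs = by_subject[sid]
        if "reference" not in devs or "test" not in devs:
            log.warning("subject %s missing a device; dropped", sid)
            continue
        pairs[sid] = (devs["reference"], devs["test"])
    if not pairs:
        raise ValueError("no subject has recordings from both devices")
    return pairs


class HRVAgreementStudy:
    """Ultra-short-term HRV validation analysis on a paired cohort.

    Parameters
    ----------
    recordings
        Iterable of :class:`~ushrv.rr.Recording` or of (reference, test)
        tuples; subjects missing either device are dropped with a warning.
    preprocess
        :class:`~ushrv.preprocess.PreprocessConfig`; defaults to strong
        artefact correction with smoothness-priors lambda = 500.
    scheme
        Segmentation windows; defaults to the nine-window design.
    """

    def __init__(
        self,
        recordings,
        preprocess: PreprocessConfig | None = None,
        scheme: list[SegmentSpec] | None = None,
    ):
        self.pairs = _pair_up(recordings)
        self.preprocess = preprocess or PreprocessConfig()
        self.scheme = scheme or default_scheme()

    # ------------------------------------------------------------------ #
    @classmethod
    def from_directory(
        cls,
        path,
        preprocess: PreprocessConfig | None = None,
        scheme=None,
        format: str = "lines_ms",
    ) -> "HRVAgreementStudy":
        """Load ``{subject}_{device}.txt`` RR files from a directory.

        Device tokens ``reference``/``ecg`` and ``test``/``pep``/``strap``
        are recognised.
        """
        alias = {
            "reference": "reference",
            "ecg": "reference",
            "test": "test",
            "pep": "test",
            "strap": "test",
        }
        path = Path(path)
        recs = []
        ext = ".csv" if format == "csv_time_interval" else ".txt"
        for f in sorted(path.glob(f"*{ext}")):
            stem = f.stem
            if "_" not in stem:
                continue
            sid, _, devtok = stem.rpartition("_")
            dev = alias.get(devtok.lower())
            if dev is None:
                log.warning("skipping %s: unrecognised device token %r", f, devtok)
                continue
            recs.append(Recording(sid, dev, read_rr(f, format)))
        if not recs:
            raise ValueError(f"no RR files found in {path}")
        return cls(recs, preprocess, scheme)

    @classmethod
    def from_synthetic(
        cls,
        n_subjects: int = 60,
        master_seed: int = 0,
        device=None,
        population=None,
        duration: float = 300.0,
        preprocess: PreprocessConfig | None = None,
        scheme=None,
    ) -> "HRVAgreementStudy":
        """Build the study on a generated paired cohort."""
        from .synthetic import generate_cohort

        pairs = generate_cohort(
            n_subjects=n_subjects,
            population=population,
            device=device,
            master_seed=master_seed,
            duration=duration,
        )
        return cls(pairs, preprocess, scheme)

    # ------------------------------------------------------------------ #
    def _metric_table(self) -> pd.DataFrame:
        rows = []
        for sid, pair in self.pairs.items():
            for rec in pair:
                for seg in self.scheme:
                    try:
                        sub = extract(rec.rr, seg)
                        m = compute_metrics(sub, self.preprocess)
                        md = m.as_dict()
                    except ValueError as exc:
                        log.warning("%s/%s/%s: %s", sid, rec.device, seg.label, exc)
                        md = {k: np.nan for k in METRIC_NAMES}
                        md.update(n_intervals=0, quality="failed")
                    rows.append(
                        {"subject_id": sid, "device": rec.device, "segment": seg.label}
                        | md
                    )
        return pd.DataFrame(rows)

    def fit(self) -> "StudyResults":
        """Compute per-cell metrics and all agreement tables."""
        metrics = self._metric_table()
        long = metrics.melt(
            id_vars=["subject_id", "device", "segment"],
            value_vars=list(METRIC_NAMES),
            var_name="metric",
            value_name="value",
        )

        descr = (
            long.groupby(["device", "segment", "metric"], sort=False)["value"]
            .agg(
                median="median",
                q25=lambda s: s.quantile(0.25),
                q75=lambda s: s.quantile(0.75),
                n="count",
            )
            .reset_index()
        )

        wide = long.pivot_table(
            index="subject_id",
            columns=["device", "segment", "metric"],
            values="value",
            sort=False,
        )

        seg_rows = []
        for device in ("reference", "test"):
            for seg in self.scheme:
                if seg.label == STANDARD_LABEL:
                    continue
                for metric in METRIC_NAMES:
                    x = wide[(device, seg.label, metric)]
                    y = wide[(device, STANDARD_LABEL, metric)]
                    seg_rows.append(
                        {
                            "device": device,
                            "segment": seg.label,
                            "metric": metric,
                            "comparison": f"segment_vs_standard:{device}",
                        }
                        | compare(x.to_numpy(), y.to_numpy()).as_dict()
                    )
        seg_agree = pd.DataFrame(seg_rows)

        dev_rows = []
        ba_points = {}
        for seg in self.scheme:
            for metric in METRIC_NAMES:
                x = wide[("reference", seg.label, metric)].to_numpy()
                y = wide[("test", seg.label, metric)].to_numpy()
                res = compare(x, y)
                dev_rows.append(
                    {
                        "segment": seg.label,
                        "metric": metric,
                        "comparison": "reference_vs_test",
                    }
                    | res.as_dict()
                )
                keep = np.isfinite(x) & np.isfinite(y)
                ba_points[(metric, seg.label)] = pd.DataFrame(
                    {
                        "subject_id": wide.index[keep],
                        "mean": (x[keep] + y[keep]) / 2.0,
                        "diff": x[keep] - y[keep],
                    }
                )
        dev_agree = pd.DataFrame(dev_rows)

        return StudyResults(
            model=self,
            metrics=metrics,
            descriptives=descr,
            segment_agreement=seg_agree,
            device_agreement=dev_agree,
            bland_altman_points=ba_points,
        )


class StudyResults:
    """Fitted tables of an :class:`HRVAgreementStudy`.

    Attributes
    ----------
    metrics : per subject x device x segment endpoint values (long table).
    descriptives : median and IQR per device x segment x metric.
    segment_agreement : the four-statistic battery, each window vs the
        standard window, within device.
    device_agreement : the battery, reference vs test device, per window.
    bland_altman_points : (metric, segment) -> per-subject (mean, diff)
        point clouds of the device comparison.
    """

    def __init__(
        self,
        model: HRVAgreementStudy,
        metrics: pd.DataFrame,
        descriptives: pd.DataFrame,
        segment_agreement: pd.DataFrame,
        device_agreement: pd.DataFrame,
        bland_altman_points: dict,
    ):
        self.model = model
        self.metrics = metrics
        self.descriptives = descriptives
        self.segment_agreement = segment_agreement
        self.device_agreement = device_agreement
        self.bland_altman_points = bland_altman_points

    # ------------------------------------------------------------------ #
    @property
    def es_table(self) -> pd.DataFrame:
        cols = ["device", "segment", "metric", "n", "d", "d_lo", "d_hi", "es_label"]
        return self.segment_agreement[cols].copy()

    @property
    def loa_table(self) -> pd.DataFrame:
        cols = ["device", "segment", "metric", "n", "bias", "loa_lower", "loa_upper"]
        return self.segment_agreement[cols].copy()

    def summary(self) -> str:
        """Human-readable digest of the fitted tables."""
        buf = io.StringIO()
        n = len(self.model.pairs)
        cfg = self.model.preprocess
        print("Ultra-short-term HRV agreement study", file=buf)
        print("=" * 60, file=buf)
        print(
            f"subjects: {n}   windows: {len(self.model.scheme)}   "
            f"artefact level: {cfg.artefact_level}   lambda: {cfg.detrend_lambda}",
            file=buf,
        )
        td = self.device_agreement.query("metric in @TIME_DOMAIN")
        fd = self.device_agreement.query("metric in @FREQ_DOMAIN")
        print("\nDevice agreement (reference vs test), ICC(2,1):", file=buf)
        print(
            f"  time-domain   min {td.icc.min():.3f}  median {td.icc.median():.3f}",
            file=buf,
        )
        print(
            f"  freq-domain   min {fd.icc.min():.3f}  median {fd.icc.median():.3f}",
            file=buf,
        )
        print("\nSegment vs standard (effect size label counts):", file=buf)
        counts = (
            self.segment_agreement.groupby(["metric", "es_label"])
            .size()
            .unstack(fill_value=0)
        )
        print(counts.to_string(), file=buf)
        print("\nDescriptives (standard 0-5 window, reference device):", file=buf)
        std = self.descriptives.query(
            "device == 'reference' and segment == @STANDARD_LABEL"
        )
        print(std.to_string(index=False, float_format=lambda v: f"{v:.2f}"), file=buf)
        return buf.getvalue()

    # ------------------------------------------------------------------ #
    def save(self, outdir) -> None:
        """Export all report tables as CSV plus a config echo and run log."""
        if self.metrics.empty:
            raise ValueError("refusing to export an empty report")
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        self.metrics.to_csv(outdir / "metrics.csv", index=False, float_format=fmt)
        self.descriptives.to_csv(
            outdir / "descriptives.csv", index=False, float_format=fmt
        )
        self.es_table.to_csv(outdir / "es_table.csv", index=False, float_format=fmt)
        self.loa_table.to_csv(outdir / "loa_table.csv", index=False, float_format=fmt)
        self.device_agreement.to_csv(
            outdir / "device_agreement.csv", index=False, float_format=fmt
        )
        ba_dir = outdir / "bland_altman_points"
        ba_dir.mkdir(exist_ok=True)
        for (metric, seg), df in self.bland_altman_points.items():
            df.to_csv(
                ba_dir / f"{metric}_{seg.replace('-', 'to')}.csv",
                index=False,
                float_format=fmt,
            )
        cfg = self.model.preprocess
        echo = {
            "n_subjects": len(self.model.pairs),
            "preprocess": {
                "artefact_level": cfg.artefact_level,
                "detrend_lambda": cfg.detrend_lambda,
                "median_window": cfg.median_window,
            },
            "segments": [
                {"label": s.label, "start_s": s.start, "end_s": s.end,
                 "class": s.window_class}
                for s in self.model.scheme
            ],
        }
        (outdir / "config_echo.yaml").write_text(yaml.safe_dump(echo, sort_keys=False))
        flagged = self.metrics.query("quality != 'ok'")
        lines = [f"subjects analysed: {len(self.model.pairs)}"]
        lines += [
            f"{r.subject_id}/{r.device}/{r.segment}: {r.quality}"
            for r in flagged.itertuples()
        ]
        (outdir / "run_log.txt").write_text("\n".join(lines) + "\n")

    def plot_bland_altman(self, metric: str, segment: str, ax=None):
        """Scatter the device-comparison Bland-Altman cloud for one cell."""
        import matplotlib.pyplot as plt

        df = self.bland_altman_points[(metric, segment)]
        row = self.device_agreement.query(
            "metric == @metric and segment == @segment"
        ).iloc[0]
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(df["mean"], df["diff"], s=12)
        ax.axhline(row.bias, color="k")
        for y in (row.loa_lower, row.loa_upper):
            ax.axhline(y, color="k", linestyle="--")
        ax.set_xlabel(f"mean of devices ({metric})")
        ax.set_ylabel("reference - test")
        ax.set_title(f"{metric}, window {segment}")
        return ax
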