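"""Chemometric evaluation metrics for calibration models.

R^2, MedAE, MAPE and RMSE are computed on the prediction (test) set, RMSEC on
the calibration (training) set, and the residual predictive deviation is
RPD = 1/sqrt(1 - R^2) -- always derived from the unrounded R^2, so the
RPD/R^2 identity holds to machine precision on every report.  All metrics are
reported on the ppm concentration scale, after inverse scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError

REPORT_COLUMNS = ("R2", "MedAE", "MAPE", "RMSE", "RPD", "RMSEC")


def _check_pair(y, yhat, min_n: int = 1):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValueError("y and yhat must have the same length")
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} samples")
    return y, yhat


def r2(y, yhat) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    y, yhat = _check_pair(y, yhat, min_n=2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise UndefinedMetricError("R^2 is undefined for constant y")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def medae(y, yhat) -> float:
    """Median absolute error (even n: midpoint of the central pair)."""
    y, yhat = _check_pair(y, yhat)
    return float(np.median(np.abs(y - yhat)))


def mape(y, yhat) -> float:
    """Mean absolute percentage error, in percent; requires nonzero truths."""
    y, yhat = _check_pair(y, yhat)
    if np.any(y == 0):
        raise UndefinedMetricError("MAPE is undefined when any y is zero")
    return float(100.0 * np.mean(np.abs((y - yhat) / y)))


def rmse(y, yhat) -> float:
    """Root mean squared error on the prediction set."""
    y, yhat = _check_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rmsec(y_train, yhat_train) -> float:
    """Root mean squared error of calibration (same formula, training set)."""
    return rmse(y_train, yhat_train)


def rpd(r2_value: float) -> float:
    """Residual predictive deviation 1/sqrt(1 - R^2); larger is better."""
    if r2_value >= 1:
        raise UndefinedMetricError("RPD is unbounded for R^2 >= 1")
    return float(1.0 / np.sqrt(1.0 - r2_value))


@dataclass
class MetricsReport:
    """One comparison-table row: R2, MedAE, MAPE, RMSE, RPD, RMSEC."""

    r2: float
    medae: float
    mape: float
    rmse: float
    rpd: float
    rmsec: float

    def as_row(self) -> tuple[float, ...]:
        return (self.r2, self.medae, self.mape, self.rmse, self.rpd, self.rmsec)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(REPORT_COLUMNS, self.as_row()))

    def to_csv(self) -> str:
        """One-row CSV with the comparison-table column order."""
        header = ",".join(REPORT_COLUMNS)
        row = ",".join(f"{v:.6g}" for v in self.as_row())
        return f"{header}\n{row}\n"

    def validate(self) -> None:
        if self.r2 > 1:
            raise UndefinedMetricError("R^2 cannot exceed 1")
        for name in ("medae", "mape", "rmse", "rmsec"):
            if getattr(self, name) < 0:
                raise UndefinedMetricError(f"{name} must be >= 0")
        expected = np.inf if self.r2 == 1 else 1.0 / np.sqrt(1.0 - self.r2)
        if not (self.rpd == expected or abs(self.rpd - expected) <= 1e-12):
            raise UndefinedMetricError("RPD does not match 1/sqrt(1 - R^2)")


def report_from_predictions(y_test, yhat_test, y_train, yhat_train) -> MetricsReport:
    """Assemble the full report; RPD uses the unrounded R^2 and becomes the
    +inf sentinel at a perfect fit instead of raising."""
    r2_value = r2(y_test, yhat_test)
    report = MetricsReport(
        r2=r2_value,
        medae=medae(y_test, yhat_test),
        mape=mape(y_test, yhat_test),
        rmse=rmse(y_test, yhat_test),
        rpd=np.inf if r2_value >= 1 else rpd(r2_value),
        rmsec=rmsec(y_train, yhat_train),
    )
    report.validate()
    return report


def evaluate(model, train_data, test_data, scaler) -> MetricsReport:
    """Score a fitted network on the ppm scale.

    ``train_data``/``test_data`` are (X, y) pairs in scaled units as consumed
    by the network; ``scaler`` maps targets back to ppm before any metric is
    computed.
    """
    from .network import predict  # late import to avoid a cycle

    X_tr, y_tr = train_data
    X_te, y_te = test_data
    yhat_tr = scaler.inverse_transform_y(predict(model, X_tr))
    yhat_te = scaler.inverse_transform_y(predict(model, X_te))
    return report_from_predictions(
        scaler.inverse_transform_y(y_te), yhat_te,
        scaler.inverse_transform_y(y_tr), yhat_tr,
    )
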