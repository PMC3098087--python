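"""Normalization variants: raw, sample (row) centering, variable (column) centering.

Normalization is always computed from — and applied to — a single set:
training and test sets are centered independently of each other, so the test
set never informs training-set preprocessing and vice versa.
"""

from __future__ import annotations

from .core import ExpressionDataset


def center_samples(data: ExpressionDataset) -> ExpressionDataset:
    """Subtract each sample's (row) mean: every row mean becomes 0."""
    values = data.values - data.values.mean(axis=1, keepdims=True)
    return data.with_values(values)


def center_variables(data: ExpressionDataset) -> ExpressionDataset:
    """Subtract each variable's (column) mean within the given set only."""
    values = data.values - data.values.mean(axis=0, keepdims=True)
    return data.with_values(values)


def normalize(data: ExpressionDataset, method: str) -> ExpressionDataset:
    if method == "raw":
        return data
    if method == "samples":
        return center_samples(data)
    if method == "variables":
        return center_variables(data)
    raise ValueError(f"unknown normalization {method!r}; use raw|samples|variables")
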