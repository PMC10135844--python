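# Vendored data

`seg_grid_synthetic.csv` — **synthetic** surrogate surveillance-risk surface.
The clinically surveyed surveillance error grid is not redistributable here,
so this table is constructed from a monotone clinical-severity scale
(`lagfuse.metrics.surrogate_risk_surface`) to satisfy the documented
properties of such a surface: zero risk on the diagonal, risk non-decreasing
as the prediction moves away from the reference, small deviations inside the
euglycaemic band staying under the risk-free cut-off of 0.5, risk categories
spanning ~0–4, and support over 20–580 mg/dL.

Layout: first row/column are the predicted/reference glucose axes
(20…580 mg/dL in 10 mg/dL steps); cell (i, j) is the unitless risk of
predicting axis[j] when the reference is axis[i]. Lookups use bilinear
interpolation. Regenerate with `lagfuse.metrics.generate_surrogate_grid()`.

Absolute risk magnitudes from this surrogate are not comparable with values
computed on the clinically derived surface; only the structural properties
above are contractual.
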