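"""Extract the standard running-kinetics variables from a stance curve.

Builds one rearfoot and one forefoot vGRF curve and prints the variables a
gait lab would report: impact and active peaks with their timing, the three
loading-rate conventions and the vertical impulse, plus the foot-strike
style read off the curve shape.
"""

from sonogait import FootStrike, extract_variables, generate_vgrf

for style in (FootStrike.REARFOOT, FootStrike.FOREFOOT):
    curve = generate_vgrf(
        style,
        impact_peak_xbw=1.51, t_impact_pct=13.5,
        active_peak_xbw=2.32, t_active_pct=42.3,
        stance_time_s=0.25,
    )
    row = extract_variables(curve)
    print(f"\n{style.value} curve ({curve.duration_s * 1e3:.0f} ms stance):")
    if row.impact_peak_found:
        print(f"  impact peak  {row.impact_peak_xbw:5.2f} xBW at {row.t_impact_peak_pct:5.1f}% stance")
    else:
        print(f"  no impact peak; deflection surrogate at {row.t_impact_peak_pct:5.1f}% stance")
    print(f"  active peak  {row.active_peak_xbw:5.2f} xBW at {row.t_active_peak_pct:5.1f}% stance")
    print(f"  loading rates LR-1/2/3: {row.lr1_xbw_s:5.1f} / "
          f"{row.lr2_xbw_s if row.lr2_xbw_s is not None else float('nan'):5.1f} / "
          f"{row.lr3_xbw_s:5.1f} xBW/s")
    print(f"  vertical impulse: {row.impulse_xbw_s:.3f} xBW*s "
          f"({row.impulse_xbw_pct:.1f} in percent-stance units)")
    print(f"  style from vGRF: {row.style_vgrf.value}")
# The rearfoot curve shows the early local maximum that defines a heel
# strike; the forefoot curve has none, so the deflection-angle scan supplies
# the surrogate impact location used for the loading rates.
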