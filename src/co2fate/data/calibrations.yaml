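# Default isotope-equilibrium thermometer calibrations.
#
# Every curve is a polynomial in x = 1000 / T[K], coefficients listed in
# ascending powers of x.  Curves are strictly decreasing in temperature over
# the stated validity range.
#
# co2_ch4: 1000 ln alpha(CO2-CH4) in permil, carbon exchange between CO2 and
#   CH4, experimental calibration of Horita (2001, GCA 65, 1907-1919):
#   1000 ln a = 0.16 + 11.754 x^2 - 2.3655 x^3 + 0.2054 x^4.
#
# d13ch3d / d12ch2d2: SYNTHETIC two-term fits (A x^2 + B x^3) for the
#   equilibrium clumped-isotopologue excesses of methane, constructed here as
#   stand-ins for the published theoretical equilibrium curves (which are not
#   reproduced in a closed form we can bundle).  Each fit is anchored to two
#   published (cap-delta, apparent temperature) equilibrium pairs and decays
#   to the stochastic limit (0 permil) at infinite temperature.  Replace with
#   a preferred published calibration by editing this file or supplying a
#   custom calibration file.
co2_ch4:
  coeffs: [0.16, 0.0, 11.754, -2.3655, 0.2054]
d13ch3d:
  coeffs: [0.0, 0.0, 0.683667, -0.0515450]
  synthetic: true
d12ch2d2:
  coeffs: [0.0, 0.0, 0.620520, 0.355777]
  synthetic: true
valid_t_range: [270.0, 700.0]
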