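"""Physical constants used throughout the package.

Forces are expressed in piconewtons (pN), lengths in nanometres (nm),
energies in pN·nm and time in seconds, which keeps every formula in this
package free of unit conversions.
"""

#: Thermal energy kB*T at 25 degrees Celsius, in pN·nm. All assays modelled
#: here are run at 25 C, so this is the package-wide default.
KBT_25C: float = 4.114
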