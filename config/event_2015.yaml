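# 2015 El Niño event scenario.
#
# The anomaly is the detrended May–December mean NINO3.4 anomaly of the
# 2015 tropical year.  Coefficients are average-country treatment effects
# per °C: the WAZ coefficient in σ-units (negative = deterioration), the
# underweight coefficient as a probability change.  Population is the
# under-5 population of the teleconnected sample countries in 2015.
anomaly_c: 1.92
waz_coefficient_per_c: -0.0406
underweight_coefficient_per_c: 0.01
under5_population: 311000000
underweight_prevalence: 0.34   # sample countries, 2015-2018 average
sdg_base_year: 2017
sdg_target_year: 2030
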