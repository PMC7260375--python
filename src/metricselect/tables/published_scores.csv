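metric_name,characteristic,auc,icc,srd_pct,eta,step2_criteria_met,step1_quality_fail
jerk_transport,smoothness transport,0.80,0.69,23.10,-4.41,0,0
log_jerk_transport,smoothness transport,0.78,0.74,26.11,-4.82,1,0
sparc_transport,smoothness transport,0.84,0.83,23.78,-7.16,0,1
n_velocity_peaks_transport,smoothness transport,0.82,0.79,21.30,-6.36,0,1
distance_to_max_velocity_transport,smoothness transport,0.44,0.74,33.64,2.42,0,1
time_to_max_velocity_transport,smoothness transport,0.45,0.78,28.70,3.93,0,1
jerk_return,smoothness return,0.84,0.68,20.83,-4.70,0,0
log_jerk_return,smoothness return,0.73,0.75,25.33,-6.08,1,0
sparc_return,smoothness return,0.71,0.76,28.93,-1.57,1,0
n_velocity_peaks_return,smoothness return,0.76,0.70,23.27,-3.28,1,1
distance_to_max_velocity_return,smoothness return,0.43,0.65,41.39,3.67,0,0
time_to_max_velocity_return,smoothness return,0.48,0.73,33.99,2.43,0,0
path_length_ratio_transport,efficiency transport,0.89,0.76,24.24,-2.17,1,0
throughput_transport,efficiency transport,0.92,0.81,24.07,-12.18,0,1
path_length_ratio_return,efficiency return,0.83,0.79,17.30,-3.61,1,0
throughput_return,efficiency return,0.90,0.78,27.43,-13.21,0,0
trajectory_error_mean_transport,curvature transport,0.55,0.86,17.14,-0.60,0,0
trajectory_error_max_transport,curvature transport,0.57,0.86,15.84,-0.37,0,0
initial_angle_theta1_transport,curvature transport,0.67,0.90,13.56,-1.50,0,1
initial_angle_theta2_transport,curvature transport,0.67,0.90,13.29,-1.52,0,1
initial_angle_theta3_transport,curvature transport,0.61,0.88,14.37,-2.06,0,0
trajectory_error_mean_return,curvature return,0.56,0.84,20.00,1.24,0,0
trajectory_error_max_return,curvature return,0.55,0.84,18.58,1.22,0,0
initial_angle_theta1_return,curvature return,0.51,0.75,33.90,3.18,0,0
initial_angle_theta2_return,curvature return,0.51,0.71,28.65,2.92,0,0
initial_angle_theta3_return,curvature return,0.60,0.79,23.99,1.53,0,0
velocity_mean_transport,speed transport,0.83,0.88,20.61,-9.99,0,0
velocity_max_transport,speed transport,0.83,0.87,18.57,-9.14,0,0
velocity_mean_return,speed return,0.75,0.87,19.01,-7.60,0,0
velocity_max_return,speed return,0.76,0.86,19.41,-6.27,1,0
position_error_peg_approach,endpoint error peg approach,0.86,0.64,29.54,-4.66,0,0
jerk_peg_approach,endpoint error peg approach,0.74,0.72,27.65,-2.94,1,0
log_jerk_peg_approach,endpoint error peg approach,0.69,0.75,30.20,-8.36,0,0
sparc_peg_approach,endpoint error peg approach,0.78,0.64,46.55,-10.29,0,0
position_error_hole_approach,endpoint error hole approach,0.94,0.76,31.29,-5.36,0,0
jerk_hole_approach,endpoint error hole approach,0.57,0.68,30.63,-4.84,0,0
log_jerk_hole_approach,endpoint error hole approach,0.66,0.83,23.25,-6.53,0,0
sparc_hole_approach,endpoint error hole approach,0.86,0.81,24.81,-5.72,1,0
haptic_collisions_mean_transport,haptic collisions transport,0.61,0.85,24.55,-3.99,0,0
haptic_collisions_max_transport,haptic collisions transport,0.63,0.84,20.54,-1.08,0,0
haptic_collisions_mean_return,haptic collisions return,0.61,0.72,25.32,-0.07,0,0
haptic_collisions_max_return,haptic collisions return,0.46,0.79,27.02,4.37,0,1
n_movement_onsets,number of movements,0.22,0.22,61.34,-0.82,0,0
n_movement_ends,number of movements,0.09,0.29,57.01,0.00,0,0
n_dropped_pegs,object drops,0.65,0.50,41.11,-3.20,0,0
gf_mean_transport,gf scaling transport,0.40,0.84,14.46,0.39,0,0
gf_max_transport,gf scaling transport,0.40,0.86,15.19,0.07,0,0
gf_rate_mean_transport,gf scaling transport,0.25,0.87,12.14,2.07,0,0
gf_rate_max_transport,gf scaling transport,0.25,0.79,20.53,3.93,0,0
gf_mean_return,gf scaling return,0.49,0.76,27.62,0.17,0,0
gf_max_return,gf scaling return,0.45,0.66,37.61,2.80,0,0
gf_rate_mean_return,gf scaling return,0.07,0.82,27.79,5.87,0,0
gf_rate_max_return,gf scaling return,0.29,0.48,34.05,7.19,0,0
gf_mean_peg_approach,gf scaling peg approach,0.45,0.83,18.09,1.10,0,0
gf_max_peg_approach,gf scaling peg approach,0.39,0.84,19.40,-0.72,0,0
gf_rate_mean_peg_approach,gf scaling peg approach,0.18,0.88,14.76,3.54,0,0
gf_rate_max_peg_approach,gf scaling peg approach,0.32,0.84,19.52,0.74,0,0
gf_mean_hole_approach,gf scaling hole approach,0.36,0.81,15.34,0.76,0,0
gf_max_hole_approach,gf scaling hole approach,0.37,0.82,16.43,0.50,0,0
gf_rate_mean_hole_approach,gf scaling hole approach,0.15,0.82,14.18,2.73,0,0
gf_rate_max_hole_approach,gf scaling hole approach,0.28,0.77,21.41,1.82,0,0
gf_rate_n_peaks_transport,gf coordination transport,0.74,0.81,20.59,-6.11,1,0
gf_rate_sparc_transport,gf coordination transport,0.74,0.82,22.48,-5.71,1,0
gf_rate_n_peaks_return,gf coordination return,0.60,0.83,20.17,-4.16,0,0
gf_rate_sparc_return,gf coordination return,0.64,0.78,23.81,-6.35,0,0
gf_rate_n_peaks_peg_approach,gf coordination peg approach,0.90,0.78,25.60,-12.25,0,0
gf_rate_sparc_peg_approach,gf coordination peg approach,0.90,0.83,22.99,-8.19,0,0
gf_rate_n_peaks_hole_approach,gf coordination hole approach,0.91,0.81,24.29,-6.14,1,0
gf_rate_sparc_hole_approach,gf coordination hole approach,0.84,0.82,26.38,-5.94,1,0
gf_rate_n_peaks_buildup,gf coordination buildup,0.15,0.44,57.70,0.77,0,1
gf_rate_sparc_buildup,gf coordination buildup,0.56,0.79,28.62,-3.22,0,1
gf_buildup_duration,gf coordination buildup,0.70,0.82,21.36,-6.97,0,0
gf_rate_n_peaks_release,gf coordination release,0.44,0.48,56.80,1.78,0,1
gf_rate_sparc_release,gf coordination release,0.91,0.86,18.63,-6.78,0,0
gf_release_duration,gf coordination release,0.67,0.81,21.63,-2.78,0,0
task_completion_time,overall disability,0.91,0.78,26.16,-11.34,0,0
simulated_noise,control,0.37,-0.07,117.04,0.25,0,1
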