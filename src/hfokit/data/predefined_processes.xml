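<processDefinitions>
  <moduleList>
    <module moduleName="fir_filter" path="builtin" />
    <module moduleName="emd_filter" path="builtin" />
    <module moduleName="rms_detector" path="builtin" />
    <module moduleName="hilbert_detector" path="builtin" />
    <module moduleName="stockwell_classifier" path="builtin" />
    <module moduleName="bump_modeling" path="builtin" />
    <module moduleName="time_features" path="builtin" />
    <module moduleName="frequency_features" path="builtin" />
    <module moduleName="svm_classifier" path="builtin" />
  </moduleList>

  <process name="fir-hilbert-stockwell">
    <reference>Hilbert-envelope detection with spectral peak/trough classification</reference>
    <activity activityName="fir" moduleRef="fir_filter">
      <inputList><input ref="input" /></inputList>
    </activity>
    <activity activityName="detect" moduleRef="hilbert_detector">
      <inputList><input ref="fir" /></inputList>
    </activity>
    <activity activityName="classify" moduleRef="stockwell_classifier">
      <inputList><input ref="detect" /><input ref="input" /></inputList>
    </activity>
    <outputList><output ref="classify" /></outputList>
  </process>

  <process name="fir-rms-stockwell">
    <reference>RMS detection with spectral peak/trough classification</reference>
    <activity activityName="fir" moduleRef="fir_filter">
      <inputList><input ref="input" /></inputList>
    </activity>
    <activity activityName="detect" moduleRef="rms_detector">
      <inputList><input ref="fir" /></inputList>
    </activity>
    <activity activityName="classify" moduleRef="stockwell_classifier">
      <inputList><input ref="detect" /><input ref="input" /></inputList>
    </activity>
    <outputList><output ref="classify" /></outputList>
  </process>

  <process name="emd-rms-stockwell">
    <reference>EMD high-pass, RMS detection, spectral peak/trough classification</reference>
    <activity activityName="emd" moduleRef="emd_filter">
      <inputList><input ref="input" /></inputList>
    </activity>
    <activity activityName="detect" moduleRef="rms_detector">
      <inputList><input ref="emd" /></inputList>
    </activity>
    <activity activityName="classify" moduleRef="stockwell_classifier">
      <inputList><input ref="detect" /><input ref="input" /></inputList>
    </activity>
    <outputList><output ref="classify" /></outputList>
  </process>

  <process name="fir-rms-bump">
    <reference>RMS detection with bump-modeling classification (reserved)</reference>
    <activity activityName="fir" moduleRef="fir_filter">
      <inputList><input ref="input" /></inputList>
    </activity>
    <activity activityName="detect" moduleRef="rms_detector">
      <inputList><input ref="fir" /></inputList>
    </activity>
    <activity activityName="classify" moduleRef="bump_modeling">
      <inputList><input ref="detect" /><input ref="input" /></inputList>
    </activity>
    <outputList><output ref="classify" /></outputList>
  </process>

  <process name="fir-rms-svm">
    <reference>RMS detection, time/frequency features, SVM classification</reference>
    <activity activityName="fir" moduleRef="fir_filter">
      <inputList><input ref="input" /></inputList>
    </activity>
    <activity activityName="detect" moduleRef="rms_detector">
      <inputList><input ref="fir" /></inputList>
    </activity>
    <activity activityName="timefeat" moduleRef="time_features">
      <inputList><input ref="detect" /><input ref="fir" /></inputList>
    </activity>
    <activity activityName="freqfeat" moduleRef="frequency_features">
      <inputList><input ref="detect" /><input ref="fir" /></inputList>
    </activity>
    <activity activityName="classify" moduleRef="svm_classifier">
      <inputList><input ref="detect" /><input ref="timefeat" /><input ref="freqfeat" /></inputList>
    </activity>
    <outputList><output ref="classify" /></outputList>
  </process>

  <process name="fir-hilbert-svm">
    <reference>Hilbert-envelope detection, time/frequency features, SVM classification</reference>
    <activity activityName="fir" moduleRef="fir_filter">
      <inputList><input ref="input" /></inputList>
    </activity>
    <activity activityName="detect" moduleRef="hilbert_detector">
      <inputList><input ref="fir" /></inputList>
    </activity>
    <activity activityName="timefeat" moduleRef="time_features">
      <inputList><input ref="detect" /><input ref="fir" /></inputList>
    </activity>
    <activity activityName="freqfeat" moduleRef="frequency_features">
      <inputList><input ref="detect" /><input ref="fir" /></inputList>
    </activity>
    <activity activityName="classify" moduleRef="svm_classifier">
      <inputList><input ref="detect" /><input ref="timefeat" /><input ref="freqfeat" /></inputList>
    </activity>
    <outputList><output ref="classify" /></outputList>
  </process>
</processDefinitions>
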